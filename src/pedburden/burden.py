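"""Per-gene rare-variant burden testing against a population reference.

Qualifying variants are rare (panel MAF below threshold) and called
deleterious by both SIFT and PolyPhen-2.  For each gene, qualifying
alternate-allele counts in the cohort probands (one proband per family)
are compared with reference-panel allele counts in a 2×2 table

    =============  ==========  ==============
                   qualifying  non-qualifying
    cohort         a           b = 2·probands − a
    reference      c           d = AN − c
    =============  ==========  ==============

with a two-sided Fisher exact p-value computed by hypergeometric
enumeration, Benjamini–Hochberg adjustment over the gene set, and
ranking; genes with adjusted p below 0.025 are flagged significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .types import (
    Cohort,
    ConfigurationError,
    DataValidationError,
)

SIGNIFICANCE_THRESHOLD = 0.025

# relative slack on the point-probability comparison, guarding against
# floating-point exclusion of tables that are exactly as extreme
_REL_TOL = 1e-7


@dataclass(frozen=True)
class QualifyingRule:
    maf_threshold: float = 0.025
    require_sift_deleterious: bool = True
    require_polyphen_damaging: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ConfigurationError(
                f"maf_threshold must be in (0, 1), got {self.maf_threshold}"
            )


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # cohort qualifying alleles
    b: int  # cohort non-qualifying alleles
    c: int  # reference qualifying alleles
    d: int  # reference non-qualifying alleles

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataValidationError("contingency cells must be >= 0")

    @property
    def odds_ratio(self) -> float:
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return math.inf if num > 0 else math.nan
        return num / den


@dataclass
class GeneBurdenResult:
    gene: str
    table: ContingencyTable
    p_raw: float
    p_adj: float = math.nan
    rank: int = 0

    @property
    def odds_ratio(self) -> float:
        return self.table.odds_ratio

    @property
    def significant(self) -> bool:
        return self.p_adj < SIGNIFICANCE_THRESHOLD


def select_qualifying(gene: str, cohort: Cohort,
                      rule: QualifyingRule = QualifyingRule()) -> list[str]:
    """Qualifying variant keys of a gene: rare in every panel where
    seen, SIFT deleterious, and PolyPhen-2 damaging/possibly damaging."""
    out = []
    for v in cohort.gene_variants(gene):
        mafs = cohort.panel.seen_mafs(v.key)
        if not all(m < rule.maf_threshold for m in mafs):
            continue
        ann = cohort.annotations.get(v.key)
        if ann is None:
            continue
        if rule.require_sift_deleterious and ann.sift != "D":
            continue
        if rule.require_polyphen_damaging and ann.polyphen not in ("D", "P"):
            continue
        out.append(v.key)
    return out


def build_table(gene: str, cohort: Cohort,
                rule: QualifyingRule = QualifyingRule(),
                qualifying: list[str] | None = None) -> ContingencyTable:
    """Assemble the cohort-vs-reference allele-count table for one gene.

    The cohort side counts alternate alleles at qualifying variants over
    the probands only (one per family); the reference side sums the
    panel's qualifying allele counts, against the panel allele number.
    """
    probands = cohort.probands
    if not probands:
        raise DataValidationError("cohort has no probands")
    if qualifying is None:
        qualifying = select_qualifying(gene, cohort, rule)
    gm = cohort.genotypes
    a = 0
    for key in qualifying:
        j = gm.variant_idx(key)
        for p in probands:
            d = int(gm.dosages[gm.sample_idx(p.sample_id), j])
            if d > 0:
                a += d
    b = 2 * len(probands) - a
    c = 0
    an_max = 0
    for key in qualifying:
        counts = cohort.panel.ref_counts(key)
        if counts is None:
            continue
        ac, an = counts
        c += ac
        an_max = max(an_max, an)
    d_cell = max(an_max - c, 0)
    return ContingencyTable(a=a, b=b, c=c, d=d_cell)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Conditioning on the margins, every table with point probability not
    exceeding that of the observed table (within a small relative
    tolerance) contributes to the p-value.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1 = a + b, a + c
    n = a + b + c + d
    if n == 0 or row1 == 0 or col1 == 0 or (b + d) == 0 or (c + d) == 0:
        return 1.0

    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    # log pmf of the hypergeometric: C(row1,k) C(n-row1, col1-k) / C(n,col1)
    logc = (_log_comb(row1, ks) + _log_comb(n - row1, col1 - ks)
            - _log_comb(n, col1))
    pmf = np.exp(logc)
    pmf /= pmf.sum()  # renormalise away log-gamma rounding
    observed = pmf[a - k_min]
    p = float(pmf[pmf <= observed * (1.0 + _REL_TOL)].sum())
    return min(p, 1.0)


def _log_comb(n: int | np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    g = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(g)
    running = 1.0
    for i in range(g - 1, -1, -1):
        rank = i + 1
        running = min(running, g * p[order[i]] / rank)
        adjusted[order[i]] = running
    return adjusted.tolist()


def run_burden(cohort: Cohort, genes: list[str],
                     rule: QualifyingRule = QualifyingRule(),
                     ) -> list[GeneBurdenResult]:
    """Fisher-test each gene, BH-adjust across the set, and rank."""
    results = []
    for gene in genes:
        table = build_table(gene, cohort, rule)
        results.append(GeneBurdenResult(
            gene=gene, table=table, p_raw=fisher_exact_two_sided(table)))
    adj = bh_adjust([r.p_raw for r in results])
    for r, p in zip(results, adj):
        r.p_adj = p
    return rank_genes(results)


def rank_genes(results: list[GeneBurdenResult]) -> list[GeneBurdenResult]:
    """Sort by adjusted p, then raw p, then gene symbol; assign ranks 1..G."""
    ranked = sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.gene))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def carrier_prevalence(carrier_counts: list[int] | tuple[int, ...],
                       cohort_size: int) -> float:
    """Percentage of the cohort carrying a variant of any class,
    rounded half-up to one decimal."""
    total = sum(carrier_counts)
    if cohort_size <= 0:
        raise DataValidationError("cohort size must be positive")
    if total > cohort_size:
        raise DataValidationError(
            f"{total} carriers exceed cohort size {cohort_size}"
        )
    from .growth import round_half_up
    return round_half_up(100.0 * total / cohort_size, 1)


def results_table(results: list[GeneBurdenResult]):
    """Results as a pandas DataFrame (gene, cells, OR, p, rank, flag)."""
    import pandas as pd
    return pd.DataFrame([{
        "gene": r.gene, "a": r.table.a, "b": r.table.b,
        "c": r.table.c, "d": r.table.d,
        "odds_ratio": r.odds_ratio, "p_raw": r.p_raw, "p_adj": r.p_adj,
        "rank": r.rank, "significant": r.significant,
    } for r in results])
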