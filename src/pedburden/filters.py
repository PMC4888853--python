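"""The variant-prioritization cascade for a dominant familial trait.

Stages, applied in order, each a pure set-reduction with a recorded
reason per removed variant:

1. quality control — at least one carrier call passes GQ/DP thresholds;
2. functional consequence — nonsense, missense, splice-site, structural,
   promoter or miRNA-deleterious changes (frameshifts kept as LoF);
3. population MAF — below threshold in every panel where seen
   ("not seen" passes);
4. segregation with trait — carried by ≥ n−1 of the n genotyped affected
   members of a family and by ≤ 1 unaffected member (unknown phenotype
   and missing genotypes excluded from both counts);
5. multiple families — the variant segregates in ≥ 2 families, or its
   gene has segregating variants in ≥ 2 distinct families;
6. optional gene allowlist (biological-relevance stand-in, off by default);
7. control screen — carried by ≤ 1 cohort control;
8. predictor consensus — called damaging by ≥ 3 of the 5 prediction tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    AnnotationRecord,
    Cohort,
    ConfigurationError,
    DataValidationError,
    PRIORITIZED_CONSEQUENCES,
    PanelAF,
    Pedigree,
)


@dataclass(frozen=True)
class FilterConfig:
    min_genotype_quality: float = 20.0
    min_depth: int = 8
    allowed_consequences: frozenset[str] = PRIORITIZED_CONSEQUENCES
    maf_threshold: float = 0.025
    max_unaffected_carriers_per_family: int = 1
    multifamily_min_families: int = 2
    max_cohort_control_carriers: int = 1
    consensus_min_tools: int = 3
    gene_allowlist: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ConfigurationError(
                f"maf_threshold must be in (0, 1), got {self.maf_threshold}"
            )
        for name in ("min_genotype_quality", "min_depth",
                     "max_unaffected_carriers_per_family",
                     "multifamily_min_families",
                     "max_cohort_control_carriers", "consensus_min_tools"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class FilterStage:
    name: str
    variants_in: int
    variants_out: int
    removed: dict[str, str] = field(default_factory=dict)


@dataclass
class FilterTrace:
    """Ordered per-stage attrition record, mirroring the flowchart."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, before: set[str], after: set[str],
            reasons: dict[str, str]) -> None:
        if not after <= before:
            raise DataValidationError(
                f"stage {name!r} produced variants not present in its input"
            )
        self.stages.append(FilterStage(
            name=name, variants_in=len(before), variants_out=len(after),
            removed={k: reasons.get(k, name) for k in sorted(before - after)},
        ))

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.variants_in, s.variants_out) for s in self.stages]

    def log_lines(self) -> list[str]:
        return [f"{s.name}: {s.variants_in} -> {s.variants_out}"
                for s in self.stages]


# ---------------------------------------------------------------------------
# per-variant predicate stages

def qc_filter(cohort: Cohort, keys: set[str],
              config: FilterConfig) -> tuple[set[str], dict[str, str]]:
    """Keep variants with >= 1 carrier call passing GQ and DP thresholds.

    Missing GQ or DP values are treated as passing.
    """
    gm = cohort.genotypes
    carriers = gm.dosages >= 1
    gq_ok = np.isnan(gm.gq) | (gm.gq >= config.min_genotype_quality)
    dp_ok = np.isnan(gm.dp) | (gm.dp >= config.min_depth)
    good = (carriers & gq_ok & dp_ok).any(axis=0)
    any_carrier = carriers.any(axis=0)
    survivors, reasons = set(), {}
    for key in keys:
        j = gm.variant_idx(key)
        if good[j]:
            survivors.add(key)
        elif not any_carrier[j]:
            reasons[key] = "no carriers in cohort"
        else:
            reasons[key] = "no carrier call passing GQ/DP"
    return survivors, reasons


def consequence_filter(cohort: Cohort, keys: set[str],
                       config: FilterConfig) -> tuple[set[str], dict[str, str]]:
    """Keep prioritized consequence classes; LoF always passes."""
    survivors, reasons = set(), {}
    for key in keys:
        ann = cohort.annotations.get(key)
        if ann is None:
            raise DataValidationError(f"variant {key} lacks annotation")
        if ann.consequence in config.allowed_consequences or ann.is_lof:
            survivors.add(key)
        else:
            reasons[key] = f"consequence {ann.consequence} not prioritized"
    return survivors, reasons


def maf_filter(keys: set[str], panel: PanelAF,
               config: FilterConfig) -> tuple[set[str], dict[str, str]]:
    """Keep variants rare (< threshold) in every panel where seen."""
    survivors, reasons = set(), {}
    for key in keys:
        mafs = panel.seen_mafs(key)
        if all(m < config.maf_threshold for m in mafs):  # not seen passes
            survivors.add(key)
        else:
            worst = max(mafs)
            reasons[key] = f"panel MAF {worst:.4g} >= {config.maf_threshold}"
    return survivors, reasons


def predictor_consensus(annotation: AnnotationRecord,
                        config: FilterConfig) -> tuple[bool, int]:
    """Count tools calling the variant damaging; pass at >= the minimum.

    Damaging calls: SIFT D, PolyPhen-2 D or P, LRT D, MutationTaster D,
    FATHMM D.
    """
    count = sum((
        annotation.sift == "D",
        annotation.polyphen in ("D", "P"),
        annotation.lrt == "D",
        annotation.mutation_taster == "D",
        annotation.fathmm == "D",
    ))
    return count >= config.consensus_min_tools, count


# ---------------------------------------------------------------------------
# family-aware stages

def segregation_filter(cohort: Cohort, key: str, pedigree: Pedigree,
                       config: FilterConfig) -> tuple[bool, dict]:
    """Evaluate segregation of one variant in one family.

    Retained iff the variant is carried by at least n−1 of the n
    genotyped affected members and by at most one genotyped unaffected
    member.  Unknown-phenotype individuals and missing genotypes are
    excluded from both counts; a variant absent from every family
    genotype is non-segregating ("absent").
    """
    gm = cohort.genotypes
    j = gm.variant_idx(key)
    n_affected = 0
    affected_carriers = 0
    unaffected_carriers = 0
    any_carrier = False
    for m in pedigree.members.values():
        if m.sample_id not in gm._sample_index:
            continue
        d = int(gm.dosages[gm.sample_idx(m.sample_id), j])
        if d < 0:  # not genotyped at this site
            continue
        carrier = d >= 1
        any_carrier = any_carrier or carrier
        if m.phenotype == "affected":
            n_affected += 1
            affected_carriers += carrier
        elif m.phenotype == "unaffected":
            unaffected_carriers += carrier
    detail = {
        "family_id": pedigree.family_id,
        "n_affected_genotyped": n_affected,
        "affected_carriers": affected_carriers,
        "unaffected_carriers": unaffected_carriers,
    }
    if not any_carrier:
        detail["reason"] = "absent"
        return False, detail
    retain = (affected_carriers >= n_affected - 1
              and unaffected_carriers
              <= config.max_unaffected_carriers_per_family)
    if not retain:
        detail["reason"] = "fails segregation rule"
    return retain, detail


def segregating_families(cohort: Cohort, keys: set[str],
                         config: FilterConfig) -> dict[str, set[str]]:
    """Map variant key → family ids in which it segregates."""
    out: dict[str, set[str]] = {k: set() for k in keys}
    for ped in cohort.pedigrees:
        for key in keys:
            ok, _ = segregation_filter(cohort, key, ped, config)
            if ok:
                out[key].add(ped.family_id)
    return out


def multifamily_filter(seg_families: dict[str, set[str]],
                       gene_of: dict[str, str],
                       config: FilterConfig) -> tuple[set[str], dict[str, str]]:
    """Keep variants segregating in >= 2 families, or in genes whose
    segregating variants span >= 2 distinct families."""
    gene_families: dict[str, set[str]] = {}
    for key, fams in seg_families.items():
        if fams:
            gene_families.setdefault(gene_of[key], set()).update(fams)
    survivors, reasons = set(), {}
    need = config.multifamily_min_families
    for key, fams in seg_families.items():
        if not fams:
            reasons[key] = "segregates in no family"
            continue
        if len(fams) >= need or len(gene_families[gene_of[key]]) >= need:
            survivors.add(key)
        else:
            reasons[key] = "single family, gene not multi-family"
    return survivors, reasons


def control_screen(cohort: Cohort, key: str,
                   config: FilterConfig) -> tuple[bool, int]:
    """Retain iff carriers among cohort controls <= the configured maximum."""
    gm = cohort.genotypes
    j = gm.variant_idx(key)
    n = sum(1 for cid in cohort.cohort_controls
            if cid in gm._sample_index
            and gm.dosages[gm.sample_idx(cid), j] >= 1)
    return n <= config.max_cohort_control_carriers, n


# ---------------------------------------------------------------------------

def run_cascade(cohort: Cohort,
                config: FilterConfig = FilterConfig(),
                ) -> tuple[list[str], list[str], FilterTrace]:
    """Run all stages in order; return candidate variants, candidate
    genes, and the full attrition trace."""
    trace = FilterTrace()
    gene_of = {v.key: v.gene for v in cohort.variants}
    current: set[str] = set(gene_of)

    for name, fn in (
            ("quality_control",
             lambda ks: qc_filter(cohort, ks, config)),
            ("consequence",
             lambda ks: consequence_filter(cohort, ks, config)),
            ("population_maf",
             lambda ks: maf_filter(ks, cohort.panel, config))):
        after, reasons = fn(current)
        trace.add(name, current, after, reasons)
        current = after

    seg = segregating_families(cohort, current, config)
    after = {k for k, fams in seg.items() if fams}
    trace.add("segregation", current, after,
              {k: "segregates in no family" for k in current - after})
    current = after

    seg = {k: seg[k] for k in current}
    after, reasons = multifamily_filter(seg, gene_of, config)
    trace.add("multiple_families", current, after, reasons)
    current = after

    if config.gene_allowlist is not None:
        after = {k for k in current if gene_of[k] in config.gene_allowlist}
        trace.add("gene_allowlist", current, after,
                  {k: "gene not on allowlist" for k in current - after})
        current = after

    after, reasons = set(), {}
    for key in current:
        ok, n = control_screen(cohort, key, config)
        if ok:
            after.add(key)
        else:
            reasons[key] = f"{n} control carriers"
    trace.add("control_screen", current, after, reasons)
    current = after

    after, reasons = set(), {}
    for key in current:
        ok, count = predictor_consensus(cohort.annotations[key], config)
        if ok:
            after.add(key)
        else:
            reasons[key] = f"only {count}/5 tools damaging"
    trace.add("predictor_consensus", current, after, reasons)
    current = after

    candidate_variants = sorted(current)
    candidate_genes = sorted({gene_of[k] for k in current})
    return candidate_variants, candidate_genes, trace
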