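"""Shared domain types for the pedigree/burden pipeline.

The pipeline reasons about biallelic variant sites, per-sample genotype
calls, family structures with affected/unaffected/unknown phenotypes,
functional annotations (consequence class plus five in-silico predictor
calls), and population-panel allele frequencies.  All coordinates are
1-based, fully closed, as in VCF; a variant is identified throughout by
its canonical key ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class PedburdenError(Exception):
    """Base class for package errors."""


class ConfigurationError(PedburdenError):
    """Invalid configuration (CLI exit code 2)."""


class DataValidationError(PedburdenError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


# Consequence classes retained by the functional-annotation filter.
PRIORITIZED_CONSEQUENCES = frozenset(
    {"nonsense", "missense", "splice_site", "structural", "promoter",
     "mirna_deleterious"}
)
ALL_CONSEQUENCES = PRIORITIZED_CONSEQUENCES | {"frameshift", "other"}

SEXES = ("male", "female")
PHENOTYPES = ("affected", "unaffected", "unknown")


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site. Multi-allelic sites are split upstream."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataValidationError(
                f"ref and alt alleles are identical at {self.chrom}:{self.pos}"
            )
        if "," in self.alt:
            raise DataValidationError(
                f"alt must be a single allele, got {self.alt!r}"
            )

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """Alternate-allele dosage for one sample at one site.

    Missing genotypes never become calls; a dosage of 0 means the sample
    was genotyped homozygous reference.  ``genotype_quality`` and
    ``depth`` are ``None`` when the VCF omits GQ/DP, in which case the
    call is treated as passing quality control.
    """

    sample_id: str
    variant_key: str
    allele_count: int
    genotype_quality: float | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.allele_count not in (0, 1, 2):
            raise DataValidationError(
                f"allele_count must be 0, 1 or 2, got {self.allele_count}"
            )
        if self.depth is not None and self.depth < 0:
            raise DataValidationError("depth must be >= 0")


@dataclass(frozen=True)
class Individual:
    sample_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "male"
    phenotype: str = "unknown"
    is_proband: bool = False
    is_cohort_control: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataValidationError(f"unknown sex {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise DataValidationError(f"unknown phenotype {self.phenotype!r}")
        if self.is_proband and self.phenotype != "affected":
            raise DataValidationError(
                f"proband {self.sample_id} must be affected"
            )


@dataclass
class Pedigree:
    """A single family: members indexed by sample id, acyclic parentage."""

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.sample_id in self.members:
            raise DataValidationError(
                f"duplicate sample id {ind.sample_id!r} in family "
                f"{self.family_id!r}"
            )
        if ind.family_id != self.family_id:
            raise DataValidationError(
                f"{ind.sample_id} belongs to family {ind.family_id!r}, "
                f"not {self.family_id!r}"
            )
        self.members[ind.sample_id] = ind

    @property
    def n_affected(self) -> int:
        return sum(1 for m in self.members.values()
                   if m.phenotype == "affected")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.members)

    def validate(self) -> None:
        """Check parent references resolve in-family and parentage is acyclic."""
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise DataValidationError(
                        f"{ind.sample_id} references parent {pid!r} absent "
                        f"from family {self.family_id!r}"
                    )
        # acyclicity: nobody may be their own ancestor (a revisit through
        # both parental lines is legitimate consanguinity, not a cycle)
        for ind in self.members.values():
            visited: set[str] = set()
            frontier = {ind.sample_id}
            while frontier:
                nxt: set[str] = set()
                for cid in frontier:
                    m = self.members[cid]
                    for p in (m.father_id, m.mother_id):
                        if p == ind.sample_id:
                            raise DataValidationError(
                                f"{ind.sample_id} is its own ancestor in "
                                f"family {self.family_id!r}"
                            )
                        if p is not None and p not in visited:
                            nxt.add(p)
                visited |= frontier
                frontier = nxt


class PanelAF:
    """Population-panel minor allele frequencies keyed by variant.

    A variant absent from the map, or absent from a particular panel,
    is "not seen" there.  Optionally carries reference allele counts
    (ac, an) per variant for burden testing against the panel.
    """

    def __init__(
        self,
        afs: Mapping[str, Mapping[str, float]] | None = None,
        ref_counts: Mapping[str, tuple[int, int]] | None = None,
    ) -> None:
        self._afs: dict[str, dict[str, float]] = {}
        self._ref: dict[str, tuple[int, int]] = dict(ref_counts or {})
        for key, panels in (afs or {}).items():
            self.set_afs(key, panels)

    def set_afs(self, key: str, panels: Mapping[str, float]) -> None:
        clean = {}
        for panel, maf in panels.items():
            if maf is None:
                continue
            if not 0.0 <= maf <= 1.0:
                raise DataValidationError(
                    f"MAF {maf} for {key} in panel {panel!r} outside [0, 1]"
                )
            clean[panel] = float(maf)
        self._afs[key] = clean

    def set_ref_counts(self, key: str, ac: int, an: int) -> None:
        if ac < 0 or an < 0 or ac > an:
            raise DataValidationError(
                f"invalid allele counts ac={ac} an={an} for {key}"
            )
        self._ref[key] = (ac, an)

    def afs(self, key: str) -> dict[str, float]:
        """Panel→MAF map for one variant; empty if never seen."""
        return dict(self._afs.get(key, {}))

    def seen_mafs(self, key: str) -> list[float]:
        return list(self._afs.get(key, {}).values())

    def ref_counts(self, key: str) -> tuple[int, int] | None:
        return self._ref.get(key)

    def keys(self) -> Iterable[str]:
        return self._afs.keys()

    def __contains__(self, key: str) -> bool:
        return key in self._afs

    def __len__(self) -> int:
        return len(self._afs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelAF):
            return NotImplemented
        return self._afs == other._afs and self._ref == other._ref


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation for one variant.

    Predictor codes follow the usual tool conventions: SIFT D/T,
    PolyPhen-2 D/P/B, LRT D/N/U, MutationTaster D/N, FATHMM D/T;
    phylop_class C (conserved) / N.
    """

    variant_key: str
    consequence: str
    sift: str = "T"
    polyphen: str = "B"
    lrt: str = "N"
    mutation_taster: str = "N"
    fathmm: str = "T"
    phylop_class: str = "N"
    gerp: float = 0.0

    _CODES = {
        "sift": {"D", "T"},
        "polyphen": {"D", "P", "B"},
        "lrt": {"D", "N", "U"},
        "mutation_taster": {"D", "N"},
        "fathmm": {"D", "T"},
        "phylop_class": {"C", "N"},
    }

    def __post_init__(self) -> None:
        if self.consequence not in ALL_CONSEQUENCES:
            raise DataValidationError(
                f"unknown consequence {self.consequence!r} for "
                f"{self.variant_key}"
            )
        for field_name, allowed in self._CODES.items():
            code = getattr(self, field_name)
            if code not in allowed:
                raise DataValidationError(
                    f"unknown {field_name} code {code!r} for "
                    f"{self.variant_key}"
                )

    @property
    def is_lof(self) -> bool:
        """Nonsense, frameshift and essential-splice changes are loss of function."""
        return self.consequence in ("nonsense", "frameshift", "splice_site")


class GenotypeMatrix:
    """Dense sample × variant alternate-allele dosage matrix.

    Dosages are 0/1/2; -1 marks a missing genotype.  GQ and DP matrices
    use NaN for "not provided".  This is the workhorse container the
    filter cascade and burden test operate on; :class:`GenotypeCall`
    objects are the record-level view produced by the readers.
    """

    def __init__(self, sample_ids: list[str], variant_keys: list[str],
                 dosages: np.ndarray,
                 gq: np.ndarray | None = None,
                 dp: np.ndarray | None = None) -> None:
        n, m = len(sample_ids), len(variant_keys)
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (n, m):
            raise DataValidationError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{n} samples x {m} variants"
            )
        self.sample_ids = list(sample_ids)
        self.variant_keys = list(variant_keys)
        self.dosages = dosages
        self.gq = (np.full((n, m), np.nan) if gq is None
                   else np.asarray(gq, dtype=float))
        self.dp = (np.full((n, m), np.nan) if dp is None
                   else np.asarray(dp, dtype=float))
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._variant_index = {k: j for j, k in enumerate(variant_keys)}
        if len(self._sample_index) != n:
            raise DataValidationError("duplicate sample ids")
        if len(self._variant_index) != m:
            raise DataValidationError("duplicate variant keys")

    def sample_idx(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def variant_idx(self, key: str) -> int:
        return self._variant_index[key]

    def dosage(self, sample_id: str, key: str) -> int:
        return int(self.dosages[self.sample_idx(sample_id),
                                self.variant_idx(key)])

    def carriers(self, key: str) -> list[str]:
        col = self.dosages[:, self.variant_idx(key)]
        return [s for s, d in zip(self.sample_ids, col) if d >= 1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.variant_keys == other.variant_keys
                and np.array_equal(self.dosages, other.dosages)
                and np.array_equal(self.gq, other.gq, equal_nan=True)
                and np.array_equal(self.dp, other.dp, equal_nan=True))


def calls_to_matrix(sample_ids: list[str], variants: list[VariantRecord],
                    calls: Iterable[GenotypeCall]) -> GenotypeMatrix:
    """Assemble record-level calls into a dense matrix (missing = -1)."""
    keys = [v.key for v in variants]
    n, m = len(sample_ids), len(keys)
    dos = np.full((n, m), -1, dtype=np.int8)
    gq = np.full((n, m), np.nan)
    dp = np.full((n, m), np.nan)
    gm = GenotypeMatrix(sample_ids, keys, np.zeros((n, m), dtype=np.int8))
    for call in calls:
        i = gm.sample_idx(call.sample_id)
        j = gm.variant_idx(call.variant_key)
        dos[i, j] = call.allele_count
        if call.genotype_quality is not None:
            gq[i, j] = call.genotype_quality
        if call.depth is not None:
            dp[i, j] = call.depth
    return GenotypeMatrix(sample_ids, keys, dos, gq, dp)


@dataclass
class Cohort:
    """Everything downstream analysis needs, in memory."""

    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    pedigrees: list[Pedigree]
    annotations: dict[str, AnnotationRecord]
    panel: PanelAF
    control_ids: list[str] = field(default_factory=list)
    growth: "object | None" = None          # pandas.DataFrame when present
    truth: dict | None = None

    def __post_init__(self) -> None:
        fam_samples: set[str] = set()
        for ped in self.pedigrees:
            overlap = fam_samples & set(ped.members)
            if overlap:
                raise DataValidationError(
                    f"samples in more than one pedigree: {sorted(overlap)}"
                )
            fam_samples |= set(ped.members)

    @property
    def variant_by_key(self) -> dict[str, VariantRecord]:
        return {v.key: v for v in self.variants}

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.gene, None)
        return list(seen)

    def gene_variants(self, gene: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.gene == gene]

    @property
    def probands(self) -> list[Individual]:
        out = []
        for ped in self.pedigrees:
            out.extend(m for m in ped.members.values() if m.is_proband)
        return out

    @property
    def cohort_controls(self) -> list[str]:
        """Sample ids of the separate cohort-control pool (non-family)."""
        return list(self.control_ids)
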