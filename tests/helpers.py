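"""Hand-construction helpers for small test cohorts."""

from __future__ import annotations

import numpy as np

from pedburden.types import (
    AnnotationRecord,
    Cohort,
    GenotypeMatrix,
    Individual,
    PanelAF,
    Pedigree,
    VariantRecord,
)


def make_variant(i: int = 0, gene: str = "GENE1") -> VariantRecord:
    return VariantRecord(chrom="chr1", pos=100 + i, ref="A", alt="T",
                         gene=gene)


def make_cohort(
    variants: list[VariantRecord],
    dosages: dict[str, list[int]],
    pedigrees: list[Pedigree] | None = None,
    annotations: dict[str, AnnotationRecord] | None = None,
    panel: PanelAF | None = None,
    controls: list[str] | None = None,
    gq: dict[str, list[float]] | None = None,
    dp: dict[str, list[float]] | None = None,
) -> Cohort:
    """Build a cohort from per-sample dosage lists (one entry per variant)."""
    sample_ids = list(dosages)
    keys = [v.key for v in variants]
    mat = np.array([dosages[s] for s in sample_ids], dtype=np.int8)
    if mat.size == 0:
        mat = mat.reshape(len(sample_ids), len(keys))
    gq_mat = (np.array([gq[s] for s in sample_ids], dtype=float)
              if gq else None)
    dp_mat = (np.array([dp[s] for s in sample_ids], dtype=float)
              if dp else None)
    gm = GenotypeMatrix(sample_ids, keys, mat, gq_mat, dp_mat)
    if annotations is None:
        annotations = {k: AnnotationRecord(variant_key=k,
                                           consequence="missense")
                       for k in keys}
    return Cohort(variants=variants, genotypes=gm,
                  pedigrees=pedigrees or [], annotations=annotations,
                  panel=panel or PanelAF(), control_ids=controls or [])


def make_family(family_id: str, members: list[tuple]) -> Pedigree:
    """Members are tuples (sid, father, mother, sex, phenotype[, proband])."""
    ped = Pedigree(family_id=family_id)
    for row in members:
        sid, father, mother, sex, pheno = row[:5]
        ped.add(Individual(
            sample_id=sid, family_id=family_id, father_id=father,
            mother_id=mother, sex=sex, phenotype=pheno,
            is_proband=bool(row[5]) if len(row) > 5 else False))
    ped.validate()
    return ped
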