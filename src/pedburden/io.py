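"""Readers and writers for the five on-disk formats.

All dialect decisions live here:

* VCF v4.2, GT format with optional per-genotype DP and GQ; multi-allelic
  sites are split into one biallelic record per ALT; missing genotypes
  yield no call.  The gene symbol is carried in the ``GENE`` INFO field.
* 6-column whitespace-delimited PED (family, id, father, mother, sex 1/2,
  phenotype 1=unaffected/2=affected/0=unknown).  The separate cohort-control
  pool is written as singleton families whose family id starts with
  ``CTRL``.  The proband of each family is, by convention, its first
  affected member in file order.
* TSV annotation table with a mandatory header row (columns ``variant_key,
  gene, consequence, sift, polyphen, lrt, mutation_taster, fathmm,
  phylop_class, gerp``).
* TSV panel allele-frequency table: ``variant_key``, one column per panel
  (blank cell = not seen in that panel), and optional reference allele
  counts ``ac``/``an``.
* CSV growth records (schema in :mod:`pedburden.growth`).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .growth import GrowthRecord
from .types import (
    AnnotationRecord,
    Cohort,
    DataValidationError,
    GenotypeCall,
    Individual,
    PanelAF,
    Pedigree,
    VariantRecord,
    calls_to_matrix,
)

CONTROL_FAMILY_PREFIX = "CTRL"

ANNOTATION_COLUMNS = [
    "variant_key", "gene", "consequence", "sift", "polyphen", "lrt",
    "mutation_taster", "fathmm", "phylop_class", "gerp",
]

GROWTH_COLUMNS = [
    "individual_id", "sex", "hsds_4", "hsds_8or9", "adult_hsds",
    "midparental_hsds", "th_sds", "age_b2_or_g2", "age_takeoff",
    "age_phv", "age_adult_height",
]


class VcfParseError(DataValidationError):
    pass


def _prevalidate_vcf(path: Path) -> None:
    """Light structural scan so parse errors can name a line number."""
    n_fixed = 8
    saw_format = False
    n_columns = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 and not line.startswith("##fileformat=VCF"):
                raise VcfParseError(
                    f"{path}:1: missing ##fileformat header line"
                )
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:n_fixed] != ["#CHROM", "POS", "ID", "REF", "ALT",
                                      "QUAL", "FILTER", "INFO"]:
                    raise VcfParseError(
                        f"{path}:{lineno}: malformed #CHROM header line"
                    )
                saw_format = len(cols) > n_fixed
                n_columns = len(cols)
                continue
            if n_columns is None:
                raise VcfParseError(
                    f"{path}:{lineno}: data line before #CHROM header"
                )
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != n_columns:
                raise VcfParseError(
                    f"{path}:{lineno}: expected {n_columns} columns, "
                    f"found {len(cols)}"
                )
    if n_columns is None:
        raise VcfParseError(f"{path}: no #CHROM header line")
    del saw_format


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[GenotypeCall]]:
    """Read a multi-sample VCF into variant records and genotype calls.

    Multi-allelic records are split into one :class:`VariantRecord` per
    ALT with per-sample allele counts recomputed against that ALT alone.
    Genotypes with any missing allele yield no call.
    """
    path = Path(path)
    _prevalidate_vcf(path)
    variants: list[VariantRecord] = []
    calls: list[GenotypeCall] = []
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for rec in vcf:
            gene = rec.INFO.get("GENE", "") or ""
            hgvs = rec.INFO.get("HGVS") or None
            gts = rec.genotypes  # [[a0, a1, phased], ...]
            dp = rec.format("DP")
            gq = rec.format("GQ")
            for alt_idx, alt in enumerate(rec.ALT, start=1):
                vr = VariantRecord(chrom=rec.CHROM, pos=rec.POS,
                                   ref=rec.REF, alt=alt, gene=gene,
                                   hgvs=hgvs)
                variants.append(vr)
                for i, sample in enumerate(samples):
                    alleles = gts[i][:-1]
                    if any(a is None or a < 0 for a in alleles):
                        continue
                    count = sum(1 for a in alleles if a == alt_idx)
                    dp_val = None
                    gq_val = None
                    if dp is not None:
                        v = float(dp[i][0] if dp.ndim > 1 else dp[i])
                        if v >= 0 and not math.isnan(v) and v < 2**30:
                            dp_val = int(v)
                    if gq is not None:
                        v = float(gq[i][0] if gq.ndim > 1 else gq[i])
                        if v >= 0 and not math.isnan(v) and v < 2**30:
                            gq_val = v
                    calls.append(GenotypeCall(
                        sample_id=sample, variant_key=vr.key,
                        allele_count=count, genotype_quality=gq_val,
                        depth=dp_val))
    except VcfParseError:
        raise
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad input
        raise VcfParseError(f"failed to parse {path}: {exc}") from exc
    return variants, calls


_PHENOTYPE_CODES = {"0": "unknown", "1": "unaffected", "2": "affected"}
_SEX_CODES = {"1": "male", "2": "female"}


def read_ped(path: str | Path,
             control_family_prefix: str = CONTROL_FAMILY_PREFIX,
             ) -> list[Pedigree]:
    """Read a 6-column PED file into pedigrees.

    Families whose id starts with ``control_family_prefix`` are the
    cohort-control pool: their members get ``is_cohort_control=True``.
    The first affected member of each non-control family (file order)
    is flagged as the proband.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise DataValidationError(
                    f"{path}:{lineno}: PED rows need >= 6 columns, "
                    f"found {len(fields)}"
                )
            rows.append((lineno, fields[:6]))

    seen_samples: set[str] = set()
    pedigrees: dict[str, Pedigree] = {}
    proband_assigned: set[str] = set()
    for lineno, (fam, sid, father, mother, sex, pheno) in (
            (ln, f) for ln, f in rows):
        if sid in seen_samples:
            raise DataValidationError(
                f"{path}:{lineno}: duplicate sample id {sid!r}"
            )
        seen_samples.add(sid)
        if sex not in _SEX_CODES:
            raise DataValidationError(
                f"{path}:{lineno}: invalid sex code {sex!r}"
            )
        if pheno not in _PHENOTYPE_CODES:
            raise DataValidationError(
                f"{path}:{lineno}: invalid phenotype code {pheno!r}"
            )
        is_control = fam.startswith(control_family_prefix)
        phenotype = _PHENOTYPE_CODES[pheno]
        is_proband = (not is_control and phenotype == "affected"
                      and fam not in proband_assigned)
        if is_proband:
            proband_assigned.add(fam)
        ind = Individual(
            sample_id=sid, family_id=fam,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_SEX_CODES[sex], phenotype=phenotype,
            is_proband=is_proband, is_cohort_control=is_control,
        )
        pedigrees.setdefault(fam, Pedigree(family_id=fam)).add(ind)

    for ped in pedigrees.values():
        ped.validate()
    return list(pedigrees.values())


def split_controls(pedigrees: list[Pedigree],
                   ) -> tuple[list[Pedigree], list[str]]:
    """Separate family pedigrees from the cohort-control singleton pool."""
    families, controls = [], []
    for ped in pedigrees:
        members = list(ped.members.values())
        if members and all(m.is_cohort_control for m in members):
            controls.extend(m.sample_id for m in members)
        else:
            families.append(ped)
    return families, controls


def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise DataValidationError(
            f"{path}: annotation header must be exactly "
            f"{ANNOTATION_COLUMNS}, found {list(df.columns)}"
        )
    out: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        key = row["variant_key"]
        if key in out:
            raise DataValidationError(
                f"{path}: duplicate variant_key {key!r}"
            )
        out[key] = AnnotationRecord(
            variant_key=key,
            consequence=row["consequence"],
            sift=row["sift"], polyphen=row["polyphen"], lrt=row["lrt"],
            mutation_taster=row["mutation_taster"], fathmm=row["fathmm"],
            phylop_class=row["phylop_class"], gerp=float(row["gerp"]),
        )
    return out


def read_panel_af(path: str | Path) -> PanelAF:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "variant_key":
        raise DataValidationError(
            f"{path}: first panel column must be 'variant_key'"
        )
    panel_cols = [c for c in df.columns[1:] if c not in ("ac", "an")]
    has_counts = "ac" in df.columns and "an" in df.columns
    panel = PanelAF()
    seen: set[str] = set()
    for _, row in df.iterrows():
        key = row["variant_key"]
        if key in seen:
            raise DataValidationError(f"{path}: duplicate variant_key {key!r}")
        seen.add(key)
        afs = {c: float(row[c]) for c in panel_cols if row[c] != ""}
        panel.set_afs(key, afs)
        if has_counts and row["ac"] != "" and row["an"] != "":
            panel.set_ref_counts(key, int(row["ac"]), int(row["an"]))
    return panel


def read_growth_csv(path: str | Path) -> list[GrowthRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != GROWTH_COLUMNS:
        raise DataValidationError(
            f"{path}: growth header must be exactly {GROWTH_COLUMNS}, "
            f"found {list(df.columns)}"
        )
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        iid = row["individual_id"]
        if iid in seen:
            raise DataValidationError(f"{path}: duplicate individual {iid!r}")
        seen.add(iid)

        def opt(col: str) -> float | None:
            return float(row[col]) if row[col] != "" else None

        records.append(GrowthRecord(
            individual_id=iid, sex=row["sex"],
            hsds_4=opt("hsds_4"), hsds_8or9=opt("hsds_8or9"),
            adult_hsds=opt("adult_hsds"),
            midparental_hsds=opt("midparental_hsds"), th_sds=opt("th_sds"),
            age_b2_or_g2=opt("age_b2_or_g2"),
            age_takeoff=opt("age_takeoff"), age_phv=opt("age_phv"),
            age_adult_height=opt("age_adult_height"),
        ))
    return records


# ---------------------------------------------------------------------------
# writers (used by the fixture emitter and the orchestrator)

def _fmt(x: float | None, nd: int = 6) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and float(x).is_integer():
        return str(int(x))
    return f"{x:.{nd}g}"


def write_vcf(path: Path, variants: list[VariantRecord],
              genotypes, qual: float = 100.0) -> None:
    """Emit a VCF v4.2 with GT:DP:GQ for all samples (text, deterministic)."""
    gm = genotypes
    contigs: dict[str, None] = {}
    for v in variants:
        contigs.setdefault(v.chrom, None)
    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID={c}>" for c in contigs),
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=HGVS,Number=1,Type=String,Description="HGVS label">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids),
    ]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for v in variants:
        j = gm.variant_idx(v.key)
        info = f"GENE={v.gene}" if v.gene else "."
        if v.hgvs:
            info += f";HGVS={v.hgvs}"
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt,
                  _fmt(qual), "PASS", info, "GT:DP:GQ"]
        for i in range(len(gm.sample_ids)):
            d = int(gm.dosages[i, j])
            if d < 0:
                fields.append("./.:.:.")
                continue
            dp = gm.dp[i, j]
            gq = gm.gq[i, j]
            dp_s = "." if math.isnan(dp) else str(int(dp))
            gq_s = "." if math.isnan(gq) else str(int(gq))
            fields.append(f"{gt_strings[d]}:{dp_s}:{gq_s}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


_PHENO_OUT = {"unknown": "0", "unaffected": "1", "affected": "2"}
_SEX_OUT = {"male": "1", "female": "2"}


def write_ped(path: Path, pedigrees: list[Pedigree],
              control_ids: list[str] | None = None) -> None:
    rows = []
    for ped in pedigrees:
        for m in ped.members.values():
            rows.append([ped.family_id, m.sample_id,
                         m.father_id or "0", m.mother_id or "0",
                         _SEX_OUT[m.sex], _PHENO_OUT[m.phenotype]])
    for cid in control_ids or []:
        rows.append([f"{CONTROL_FAMILY_PREFIX}_{cid}", cid, "0", "0",
                     "1", "1"])
    path.write_text(
        "\n".join("\t".join(r) for r in rows) + ("\n" if rows else ""))


def write_annotation_table(path: Path,
                           annotations: dict[str, AnnotationRecord],
                           genes: dict[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for key, ann in annotations.items():
            w.writerow([key, genes.get(key, ""), ann.consequence,
                        ann.sift, ann.polyphen, ann.lrt,
                        ann.mutation_taster, ann.fathmm,
                        ann.phylop_class, f"{ann.gerp:.3f}"])


def write_panel_af(path: Path, panel: PanelAF,
                   panel_names: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_key", *panel_names, "ac", "an"])
        for key in panel.keys():
            afs = panel.afs(key)
            counts = panel.ref_counts(key)
            row = [key] + [f"{afs[p]:.6g}" if p in afs else ""
                           for p in panel_names]
            row += ([str(counts[0]), str(counts[1])] if counts else ["", ""])
            w.writerow(row)


def write_growth_csv(path: Path, records: list[GrowthRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(GROWTH_COLUMNS)
        for r in records:
            w.writerow([
                r.individual_id, r.sex,
                *(("" if x is None else f"{x:.4f}") for x in (
                    r.hsds_4, r.hsds_8or9, r.adult_hsds,
                    r.midparental_hsds, r.th_sds, r.age_b2_or_g2,
                    r.age_takeoff, r.age_phv, r.age_adult_height)),
            ])


def load_cohort(vcf_path: str | Path, ped_path: str | Path,
                annotation_path: str | Path, panel_path: str | Path,
                growth_path: str | Path | None = None) -> Cohort:
    """Read the five fixture files into an in-memory :class:`Cohort`."""
    variants, calls = read_vcf(vcf_path)
    pedigrees = read_ped(ped_path)
    families, controls = split_controls(pedigrees)
    sample_ids = [s for ped in pedigrees for s in ped.members]
    gm = calls_to_matrix(sample_ids, variants, calls)
    annotations = read_annotation_table(annotation_path)
    panel = read_panel_af(panel_path)
    growth = read_growth_csv(growth_path) if growth_path else None
    return Cohort(variants=variants, genotypes=gm, pedigrees=families,
                  annotations=annotations, panel=panel,
                  control_ids=controls, growth=growth)
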