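"""Synthetic cohort generator for the downstream pipeline.

Emulates a familial delayed-puberty study design: multi-generation
families segregating an autosomal-dominant trait with configurable
penetrance and phenocopy rate, one planted causal gene carrying rare
heterozygous variants, background variants at panel-matched
frequencies, a separate cohort-control pool, and per-individual growth
records.  Founders draw alleles at panel minor-allele frequencies; one
founder per family is seeded heterozygous for the family's causal
variant; transmission is Mendelian with a fair allele choice.  The
whole cohort is generated from a single seeded random stream, so a
given config+seed always yields an identical cohort and byte-identical
fixture files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .growth import GrowthRecord
from .types import (
    AnnotationRecord,
    Cohort,
    ConfigurationError,
    GenotypeMatrix,
    Individual,
    PanelAF,
    Pedigree,
    VariantRecord,
)

PANEL_NAMES = ["finnish", "european"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class MAFMixture:
    """Two-component Beta mixture over [0, 0.5] for background MAFs.

    The rare component dominates (exome variation is mostly rare); the
    common component supplies variants that the MAF filter must remove.
    """

    rare_weight: float = 0.7
    rare_alpha: float = 0.4
    rare_beta: float = 40.0
    common_alpha: float = 2.0
    common_beta: float = 5.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        rare = rng.random(n) < self.rare_weight
        out = np.where(
            rare,
            rng.beta(self.rare_alpha, self.rare_beta, n),
            rng.beta(self.common_alpha, self.common_beta, n),
        ) * 0.5
        return np.clip(out, 1e-5, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 20
    family_generations: int = 3
    mean_children_per_couple: float = 2.5
    causal_gene: str = "CAUSAL1"
    n_causal_variants: int = 4
    causal_panel_maf: float = 0.005
    penetrance: float = 1.0
    phenocopy_rate: float = 0.02
    n_background_genes: int = 100
    background_variants_per_gene: int = 5
    background_maf_distribution: MAFMixture = field(default_factory=MAFMixture)
    n_cohort_controls: int = 100
    population_baseline_dp_rate: float = 0.02
    unknown_minor_fraction: float = 0.1
    reference_an: int = 10000
    affected_delta_hsds_shift: float = -0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("need at least one family")
        n_genes = self.n_background_genes + (1 if self.n_causal_variants else 0)
        if n_genes < 1:
            raise ConfigurationError("need at least one gene")
        if self.family_generations not in (2, 3):
            raise ConfigurationError("family_generations must be 2 or 3")
        if self.mean_children_per_couple <= 0:
            raise ConfigurationError("mean_children_per_couple must be > 0")
        for name in ("penetrance", "phenocopy_rate",
                     "population_baseline_dp_rate", "unknown_minor_fraction",
                     "causal_panel_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_causal_variants and not self.causal_panel_maf < 0.025:
            raise ConfigurationError(
                "causal_panel_maf must be < 0.025 so planted variants "
                "survive the MAF filter by construction"
            )
        for name in ("n_causal_variants", "n_background_genes",
                     "background_variants_per_gene", "n_cohort_controls",
                     "reference_an"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class SimulatedCohort:
    cohort: Cohort
    config: SimulationConfig

    @property
    def truth(self) -> dict:
        return self.cohort.truth


# pubertal-milestone age means (years) by sex and trait status; the
# affected means sit beyond and the unaffected means below the
# diagnostic cut-offs (onset > 13.5/13.0, takeoff > 12.9/11.3,
# PHV > 14.8/12.8, adult height > 18/16 for males/females)
_MILESTONES = {
    ("male", True): {"onset": 15.5, "takeoff": 15.5, "phv": 16.3,
                     "adult": 18.9},
    ("male", False): {"onset": 12.0, "takeoff": 11.3, "phv": 13.5,
                      "adult": 17.0},
    ("female", True): {"onset": 14.2, "takeoff": 13.0, "phv": 14.2,
                       "adult": 16.9},
    ("female", False): {"onset": 10.8, "takeoff": 10.0, "phv": 11.5,
                        "adult": 15.0},
}
_MILESTONE_SD = 0.5


def _make_variants(config: SimulationConfig,
                   rng: np.random.Generator,
                   ) -> tuple[list[VariantRecord], np.ndarray, list[str]]:
    """Variant records, their generating MAFs, and causal keys."""
    variants: list[VariantRecord] = []
    mafs: list[float] = []
    causal_keys: list[str] = []

    for j in range(config.n_causal_variants):
        ref, alt = _draw_alleles(rng)
        v = VariantRecord(chrom="chr3", pos=1_000_000 + 1000 * j,
                          ref=ref, alt=alt, gene=config.causal_gene)
        variants.append(v)
        mafs.append(config.causal_panel_maf)
        causal_keys.append(v.key)

    bg_mafs = config.background_maf_distribution.sample(
        rng, config.n_background_genes * config.background_variants_per_gene)
    idx = 0
    for g in range(config.n_background_genes):
        gene = f"BG{g + 1:04d}"
        chrom = f"chr{(g % 22) + 1}"
        for j in range(config.background_variants_per_gene):
            ref, alt = _draw_alleles(rng)
            v = VariantRecord(chrom=chrom,
                              pos=10_000_000 + 100_000 * g + 100 * j,
                              ref=ref, alt=alt, gene=gene)
            variants.append(v)
            mafs.append(float(bg_mafs[idx]))
            idx += 1
    return variants, np.asarray(mafs), causal_keys


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return _BASES[i], _BASES[j]


def _founder_dosages(rng: np.random.Generator,
                     mafs: np.ndarray) -> np.ndarray:
    return rng.binomial(2, mafs).astype(np.int8)


def _transmit(rng: np.random.Generator, father: np.ndarray,
              mother: np.ndarray) -> np.ndarray:
    """Mendelian transmission with fair allele choice, per variant."""
    m = father.size
    from_f = (rng.random(m) < father / 2.0).astype(np.int8)
    from_m = (rng.random(m) < mother / 2.0).astype(np.int8)
    return from_f + from_m


def _make_annotations(variants: list[VariantRecord], causal: set[str],
                      rng: np.random.Generator,
                      ) -> dict[str, AnnotationRecord]:
    anns: dict[str, AnnotationRecord] = {}
    for v in variants:
        if v.key in causal:
            # rare heterozygous missense profile: damaging consensus and
            # SIFT+PolyPhen deleterious, like the discovery variants
            anns[v.key] = AnnotationRecord(
                variant_key=v.key, consequence="missense",
                sift="D", polyphen="D", lrt="D", mutation_taster="D",
                fathmm="D" if rng.random() < 0.5 else "T",
                phylop_class="C", gerp=float(f"{rng.normal(5.0, 0.4):.3f}"))
            continue
        cons = str(rng.choice(
            ["other", "missense", "nonsense", "splice_site", "promoter"],
            p=[0.45, 0.40, 0.03, 0.05, 0.07]))
        if cons == "missense":
            sift = "D" if rng.random() < 0.35 else "T"
            polyphen = str(rng.choice(["D", "P", "B"], p=[0.25, 0.15, 0.60]))
            lrt = "D" if rng.random() < 0.30 else "N"
            mt = "D" if rng.random() < 0.40 else "N"
            fathmm = "D" if rng.random() < 0.25 else "T"
        else:
            sift = "D" if rng.random() < 0.10 else "T"
            polyphen = "B"
            lrt = "N"
            mt = "D" if rng.random() < 0.10 else "N"
            fathmm = "T"
        anns[v.key] = AnnotationRecord(
            variant_key=v.key, consequence=cons, sift=sift,
            polyphen=polyphen, lrt=lrt, mutation_taster=mt, fathmm=fathmm,
            phylop_class="C" if rng.random() < 0.4 else "N",
            gerp=float(f"{rng.normal(2.0, 2.0):.3f}"))
    return anns


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full desk-scale cohort, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    variants, mafs, causal_keys = _make_variants(config, rng)
    m = len(variants)
    causal_idx = np.array(
        [i for i, v in enumerate(variants) if v.key in set(causal_keys)],
        dtype=int)

    sample_ids: list[str] = []
    dosages: list[np.ndarray] = []
    pedigrees: list[Pedigree] = []
    parents: dict[str, tuple[str | None, str | None]] = {}
    generation: dict[str, int] = {}
    sexes: dict[str, str] = {}
    fam_of: dict[str, str] = {}

    def new_sample(fam: str, sex: str, gen: int, dose: np.ndarray,
                   father: str | None = None,
                   mother: str | None = None) -> str:
        sid = f"{fam}_{len([s for s in sample_ids if fam_of.get(s) == fam]) + 1:02d}"
        sample_ids.append(sid)
        dosages.append(dose)
        parents[sid] = (father, mother)
        generation[sid] = gen
        sexes[sid] = sex
        fam_of[sid] = fam
        return sid

    for f in range(config.n_families):
        fam = f"FAM{f + 1:03d}"
        founder_f = _founder_dosages(rng, mafs)
        founder_m = _founder_dosages(rng, mafs)
        if config.n_causal_variants:
            # seed exactly one causal allele into one grand-founder
            v_idx = causal_idx[f % len(causal_idx)]
            seeded = founder_f if rng.random() < 0.5 else founder_m
            other = founder_m if seeded is founder_f else founder_f
            seeded[causal_idx] = 0
            other[causal_idx] = 0
            seeded[v_idx] = 1
        gf = new_sample(fam, "male", 1, founder_f)
        gm_ = new_sample(fam, "female", 1, founder_m)

        n_children = max(1, int(rng.poisson(config.mean_children_per_couple)))
        children = []
        for _ in range(n_children):
            sex = "male" if rng.random() < 0.5 else "female"
            dose = _transmit(rng, founder_f, founder_m)
            children.append(new_sample(fam, sex, 2, dose, gf, gm_))

        if config.family_generations == 3:
            for child in children:
                if rng.random() >= 0.7:
                    continue
                n_gc = int(rng.poisson(config.mean_children_per_couple))
                if n_gc == 0:
                    continue
                spouse_sex = "female" if sexes[child] == "male" else "male"
                spouse = new_sample(fam, spouse_sex, 2,
                                    _founder_dosages(rng, mafs))
                father, mother = ((child, spouse)
                                  if sexes[child] == "male"
                                  else (spouse, child))
                for _ in range(n_gc):
                    sex = "male" if rng.random() < 0.5 else "female"
                    dose = _transmit(rng, dosages[sample_ids.index(father)],
                                     dosages[sample_ids.index(mother)])
                    new_sample(fam, sex, 3, dose, father, mother)

        pedigrees.append(Pedigree(family_id=fam))

    control_ids = []
    for c in range(config.n_cohort_controls):
        sid = f"C{c + 1:04d}"
        sample_ids.append(sid)
        dosages.append(_founder_dosages(rng, mafs))
        sexes[sid] = "male" if rng.random() < 0.5 else "female"
        generation[sid] = 0
        fam_of[sid] = ""
        parents[sid] = (None, None)
        control_ids.append(sid)

    dose_mat = np.vstack(dosages) if dosages else np.zeros((0, m), np.int8)

    # phenotypes
    baseline = max(config.phenocopy_rate, config.population_baseline_dp_rate)
    is_carrier = ((dose_mat[:, causal_idx] >= 1).any(axis=1)
                  if causal_idx.size else np.zeros(len(sample_ids), bool))
    phenotype: dict[str, str] = {}
    for i, sid in enumerate(sample_ids):
        if sid in control_ids:
            phenotype[sid] = "unaffected"
            continue
        p_aff = config.penetrance if is_carrier[i] else baseline
        phenotype[sid] = ("affected" if rng.random() < p_aff
                          else "unaffected")

    # probands: first affected member of each family, in member order
    proband_of: dict[str, str] = {}
    for sid in sample_ids:
        fam = fam_of[sid]
        if fam and fam not in proband_of and phenotype[sid] == "affected":
            proband_of[fam] = sid

    # a fraction of third-generation minors has unknown status
    # (too young to diagnose); never the proband
    for sid in sample_ids:
        if (generation.get(sid) == 3
                and proband_of.get(fam_of[sid]) != sid
                and rng.random() < config.unknown_minor_fraction):
            phenotype[sid] = "unknown"

    # assemble pedigrees
    peds_by_id = {p.family_id: p for p in pedigrees}
    for sid in sample_ids:
        fam = fam_of[sid]
        if not fam:
            continue
        father, mother = parents[sid]
        peds_by_id[fam].add(Individual(
            sample_id=sid, family_id=fam, father_id=father,
            mother_id=mother, sex=sexes[sid], phenotype=phenotype[sid],
            is_proband=proband_of.get(fam) == sid,
            is_cohort_control=False))
    for ped in pedigrees:
        ped.validate()

    # per-genotype depth and quality (a light tail of low-quality calls
    # exercises the QC stage without routinely destroying variants)
    n = len(sample_ids)
    dp = rng.poisson(30, size=(n, m)).astype(float)
    gq = np.clip(rng.normal(80.0, 18.0, size=(n, m)), 2.0, 99.0).round()
    gm_mat = GenotypeMatrix(sample_ids, [v.key for v in variants],
                            dose_mat, gq, dp)

    # panel: the generating MAF verbatim in the first panel, jittered in
    # the second (bounded so rarity class is preserved); absent rarely
    panel = PanelAF()
    jitter = np.exp(rng.normal(0.0, 0.2, size=m)).clip(0.5, 2.0)
    seen2 = rng.random(m) < 0.9
    for i, v in enumerate(variants):
        # frequencies go through their on-disk 6-significant-digit
        # representation so a written fixture reads back identically
        afs = {PANEL_NAMES[0]: float(f"{mafs[i]:.6g}")}
        if seen2[i]:
            afs[PANEL_NAMES[1]] = float(
                f"{np.clip(mafs[i] * jitter[i], 1e-6, 0.5):.6g}")
        panel.set_afs(v.key, afs)
        an = config.reference_an
        panel.set_ref_counts(v.key, int(round(an * mafs[i])), an)

    annotations = _make_annotations(variants, set(causal_keys), rng)

    growth = _make_growth(sample_ids, fam_of, sexes, phenotype,
                          config, rng)

    truth = {
        "causal_gene": config.causal_gene if config.n_causal_variants else None,
        "causal_variants": causal_keys,
        "carriers": [sid for i, sid in enumerate(sample_ids)
                     if is_carrier[i]],
    }
    cohort = Cohort(variants=variants, genotypes=gm_mat,
                    pedigrees=pedigrees, annotations=annotations,
                    panel=panel, control_ids=control_ids,
                    growth=growth, truth=truth)
    return SimulatedCohort(cohort=cohort, config=config)


def _make_growth(sample_ids, fam_of, sexes, phenotype, config, rng,
                 ) -> list[GrowthRecord]:
    records = []
    shift = config.affected_delta_hsds_shift
    for sid in sample_ids:
        if not fam_of[sid]:
            continue  # growth records only for family members
        sex = sexes[sid]
        affected = phenotype[sid] == "affected"
        mid = float(rng.normal(0.0, 0.6))
        h4 = float(rng.normal(mid, 0.7))
        h89 = h4 + (shift if affected else 0.0) + float(rng.normal(0, 0.15))
        adult = h4 + float(rng.normal(0, 0.3))
        if phenotype[sid] == "unknown":
            ages = dict(onset=None, takeoff=None, phv=None, adult=None)
        else:
            means = _MILESTONES[(sex, affected)]
            ages = {k: round(float(rng.normal(mu, _MILESTONE_SD)), 4)
                    for k, mu in means.items()}
        records.append(GrowthRecord(
            individual_id=sid, sex=sex, hsds_4=round(h4, 4),
            hsds_8or9=round(h89, 4), adult_hsds=round(adult, 4),
            midparental_hsds=round(mid, 4), th_sds=None,
            age_b2_or_g2=ages["onset"], age_takeoff=ages["takeoff"],
            age_phv=ages["phv"], age_adult_height=ages["adult"]))
    return records


def validate_mendelian(cohort: Cohort) -> None:
    """Check every child allele is traceable to a genotyped parent."""
    gm = cohort.genotypes
    for ped in cohort.pedigrees:
        for ind in ped.members.values():
            if ind.father_id is None or ind.mother_id is None:
                continue
            ci = gm.sample_idx(ind.sample_id)
            fi = gm.sample_idx(ind.father_id)
            mi = gm.sample_idx(ind.mother_id)
            child = gm.dosages[ci]
            fa, mo = gm.dosages[fi], gm.dosages[mi]
            ok = np.ones(child.size, bool)
            ok &= ~((child >= 1) & (fa <= 0) & (mo <= 0))
            ok &= ~((child == 2) & ((fa <= 0) | (mo <= 0)))
            if not ok.all():
                j = int(np.where(~ok)[0][0])
                raise AssertionError(
                    f"Mendelian inconsistency for {ind.sample_id} at "
                    f"{gm.variant_keys[j]}"
                )


def write_fixture_set(sim: SimulatedCohort | Cohort,
                      directory: str | Path) -> dict:
    """Write VCF, PED, annotation TSV, panel TSV, growth CSV and truth
    JSON; return a manifest with per-file SHA-256 checksums."""
    cohort = sim.cohort if isinstance(sim, SimulatedCohort) else sim
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create {directory}: {exc}") from exc

    paths = {
        "vcf": directory / "cohort.vcf",
        "ped": directory / "cohort.ped",
        "annotations": directory / "annotations.tsv",
        "panel": directory / "panel_af.tsv",
        "growth": directory / "growth.csv",
        "truth": directory / "truth.json",
    }
    cio.write_vcf(paths["vcf"], cohort.variants, cohort.genotypes)
    cio.write_ped(paths["ped"], cohort.pedigrees, cohort.control_ids)
    cio.write_annotation_table(
        paths["annotations"], cohort.annotations,
        {v.key: v.gene for v in cohort.variants})
    cio.write_panel_af(paths["panel"], cohort.panel, PANEL_NAMES)
    cio.write_growth_csv(paths["growth"], cohort.growth or [])
    paths["truth"].write_text(
        json.dumps(cohort.truth or {}, indent=2, sort_keys=True) + "\n")

    manifest = {"files": {}}
    for name, path in paths.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"path": path.name, "sha256": digest}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
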