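# Methods

## Design overview

`pedburden` implements the three statistical components of a
family-based rare-variant discovery study for an autosomal-dominant
trait — variant prioritization by segregation, gene-collapsing burden
testing, and auxological phenotyping — together with a synthetic-cohort
generator that supplies inputs with the statistical structure the
analysis assumes.  All randomness flows from a single seeded
`numpy.random.Generator` per cohort; identical configuration and seed
give identical in-memory cohorts and byte-identical fixture files.

## Data model and formats

Coordinates are 1-based and fully closed, as in VCF; every variant is
identified by the canonical key `chrom:pos:ref:alt`, so indels are
unambiguous and multi-allelic sites (split on read, one record per ALT
with per-ALT allele counts) cannot collide.  Genotypes live in a dense
sample × variant dosage matrix (0/1/2, −1 for missing); genotypes with
any missing allele yield no call.  Missing per-genotype DP or GQ is
treated as passing quality control, since absent FORMAT fields carry no
evidence against a call.  PED phenotype codes follow convention
(0 unknown, 1 unaffected, 2 affected).  Two conventions are layered on
the 6-column PED rather than extending it: the cohort-control pool is
written as singleton families whose id starts with `CTRL`, and the
proband of each family is its first affected member in file order.

## Filter cascade

Stages run in the order quality control → consequence → population
MAF → segregation → multiple families → (optional gene allowlist) →
control screen → predictor consensus.  Each stage is a pure set
reduction, so the trace is monotone by construction; the first four
per-variant predicates (QC, consequence, MAF, consensus) commute, which
the test suite checks on simulated cohorts over all 24 orderings.

Decisions that were genuinely open, and how they were fixed:

* **QC thresholds.** GQ ≥ 20 and DP ≥ 8 are this package's defaults —
  conventional exome values for a confident heterozygous call.  A
  variant survives if *any* carrier call passes, because one confident
  observation establishes the allele's presence.
* **Segregation counts.** The rule "≥ n−1 affected carriers and ≤ 1
  unaffected carrier" is evaluated per family with *n* defined as the
  number of *genotyped* affected members; individuals of unknown
  phenotype (too young to diagnose, insufficient growth data) and
  missing genotypes are excluded from both counts because they carry no
  trait information.  A variant absent from all family genotypes is
  non-segregating regardless of *n*.  Globally a variant passes the
  stage if it segregates in at least one family; the multiple-family
  stage then demands two families at the variant or gene level.
* **Control screen.** "Present in ≤ 1 control" is applied to carrier
  counts, not allele counts; the trait model is dominant and all
  simulated causal alleles are heterozygous, so the two coincide.  The
  screen uses the full control pool.
* **MAF conjunction.** The threshold must hold in every panel where the
  variant is seen; variants absent from all panels pass, since absence
  from a reference panel cannot make a variant common.
* **Biological relevance.** The original design's
  linkage-disequilibrium/annotation prioritization is out of scope;
  the stage survives as an optional gene-allowlist predicate, off by
  default.

## Burden test

Qualifying variants are rare (MAF < 2.5 % in every panel where seen)
and called deleterious by both SIFT and PolyPhen-2 (D or P).  Cells are
allele counts: with one proband per family, a = qualifying alternate
alleles over probands, b = 2·probands − a; the reference side sums the
panel's per-variant qualifying allele counts (c = Σ AC) against the
panel allele number (d = AN − c, with AN taken as the maximum AN over
the gene's qualifying variants — panels generated here use one AN
throughout).  Allele-based counting was chosen because the comparison
is against population allele frequencies; carrier-based counting gives
the same qualitative behavior for rare heterozygous variants.

The two-sided Fisher exact p-value is computed by full enumeration of
the hypergeometric support, using the point-probability ("minimum
likelihood") definition standard in exact-test implementations: all
tables with the observed margins whose probability does not exceed that
of the observed table contribute.  Probabilities come from log-gamma
binomial coefficients, renormalized over the support; the ≤ comparison
carries a relative tolerance of 1e−7 so that tables exactly as extreme
are not lost to floating-point rounding.  The support never exceeds
min(row, column) margin + 1 terms, so the enumeration is O(margin) even
against a reference panel of 10⁴–10⁶ alleles.  Benjamini–Hochberg
adjustment is the usual step-up: adjusted p(i) = min over j ≥ i of
G·p(j)/j, capped at 1, mapped back to input order.  Genes are ranked by
(adjusted p, raw p, symbol) — the lexicographic tail makes ranking
deterministic under ties — and flagged significant at adjusted
p < 0.025.  Both the Fisher and BH implementations are verified in the
tests against independent references (`scipy.stats.fisher_exact`,
`statsmodels.multipletests`) to 1e−10 on a thousand random inputs.

Carrier prevalence is reported as 100·carriers/N rounded half-up to one
decimal, matching how such figures are conventionally printed.

## Growth analytics

Target height SDS is 0.886·x − 0.071 for boys and 0.791·x − 0.147 for
girls, where x is the mean parental height SDS.  Distance to target is
oriented TH − HSDS, the orientation that renders short-for-target
children as positive distances in the published proband table the
package bundles; ΔHSDS is HSDS(8/9) − HSDS(4).  Screening limits
(ΔHSDS 1.21; distance 1.76 / 1.72 / 1.44 at 4 y / 8–9 y / adult) are
applied with "< limit is normal": a value at the limit is abnormal.
Distances are compared as signed values (only short-for-target is
flagged); ΔHSDS is compared in magnitude, treating the published
screening limit as a bound on change in either direction.  Diagnostic
age thresholds use strict ">" comparisons.  Computed SDS quantities are
reported rounded half-up to one decimal, as in clinical tables; missing
inputs flag a metric "not evaluable" rather than raising.

## Synthetic cohort generator

Each family has a founder couple, a Poisson(2.5, ≥ 1) sibship, and
(for three-generation families) grandchildren through married-in
founder spouses; 20 families, ~280 genotyped individuals and a separate
pool of 100 cohort controls by default.  Founders draw dosages
Binomial(2, MAF) per variant; one grand-founder per family is seeded
heterozygous for the family's causal variant (families cycle through
the configured causal variants) with other causal dosages in the
founder couple zeroed, so each family introduces exactly one seeded
causal allele; married-in spouses and controls draw causal alleles at
panel MAF like any rare variant.  Transmission is Mendelian with fair
allele choice, independent across sites (no linkage — the pipeline
never uses position beyond identity).

Phenotype: carriers of ≥ 1 causal allele are affected with probability
`penetrance` (default 1.0, the cleanest benchmark condition; reduced
values model the incomplete penetrance real families show); other
family members are affected with probability max(phenocopy rate,
population baseline rate) — defaults 0.02, consistent with a trait
defined as the ≥ 2 SD tail of a population distribution, and producing
the occasional affected non-carrier that the segregation rule must
tolerate.  A configurable fraction (default 0.1) of third-generation
members is relabeled "unknown" to exercise the filter's
unknown-handling; the proband (first affected member) is never
relabeled.  Background variants populate 100 genes × 5 variants with
MAFs from a two-component Beta mixture on [0, 0.5] (70 % rare,
Beta(0.4, 40); 30 % common, Beta(2, 5)) so that the MAF filter has both
survivors and casualties.  Annotations give causal variants the profile
of the discovery-class variants (missense, SIFT/PolyPhen/LRT/
MutationTaster deleterious, conserved); background predictor calls are
drawn with tool-plausible marginal rates.  Reference panel counts are
deterministic, AC = round(AN·MAF) at AN = 10 000, i.e. the reference
is exactly at its nominal frequencies.  Per-genotype DP ~ Poisson(30)
and GQ ~ N(80, 18) clipped to [2, 99] give a light low-quality tail.

Growth records: each individual gets a mid-parental HSDS ~ N(0, 0.6),
HSDS(4) ~ N(mid, 0.7), HSDS(8/9) = HSDS(4) + shift + N(0, 0.15) with
shift −0.3 for affected individuals (the mild prepubertal decline
typical of the phenotype), and milestone ages drawn N(μ, 0.5) with
affected/unaffected means straddling the diagnostic cut-offs.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: linkage and haplotype structure,
population stratification between cohort and reference, sequencing
batch effects and genotyping error, ascertainment bias in family
recruitment, de-novo mutation, and any dependence between a variant's
annotation profile and its true effect beyond the planted gene.  The
recovery benchmarks show the pipeline is correct and well calibrated
under its own assumptions, not that those assumptions hold in any
particular study.

## Numerical choices and degenerate inputs

Fisher p is defined as 1 whenever a margin of the table is zero (an
empty qualifying class carries no evidence).  The odds ratio is ∞ when
only the denominator product is zero and NaN for 0/0.  BH on an empty
vector returns an empty vector; p-values outside [0, 1] raise.  An
empty cohort flows through the cascade to empty candidate sets with a
zero-count trace.  Genes with no qualifying variants produce a = c = 0
tables (p = 1) rather than being dropped, so the multiplicity
correction always spans the full tested set.

## Benchmark problem sizes

The acceptance script and the corresponding tests use: 1 000 random
2×2 tables (cells ≤ 50) for the Fisher cross-check; 1 000 random
p-vectors (length ≤ 39) for BH; all 2^m carrier configurations of
eight pedigree shapes up to 8 members (1 176 evaluations) for the
segregation oracle; 50 seeded cohorts (20 families, penetrance 1.0,
4 causal variants at 0.5 % panel MAF, 100 background genes) for
planted-gene recovery; and 20 seeded null cohorts (no causal gene,
100 genes) for calibration.  These sizes make every property estimate
stable while keeping the whole script under a minute on one CPU.

## Known limitations

* The pipeline tests a dominant, single-gene architecture; recessive
  and compound-heterozygous models, X-linkage and digenic effects are
  out of scope.
* The burden comparison assumes the reference panel is
  ancestry-matched; no stratification correction is applied.
* Heights must already be expressed as SDS against a national
  reference; raw height conversion is not provided.
* Predictor calls are consumed as annotation input; the package never
  re-derives SIFT/PolyPhen/LRT/MutationTaster/FATHMM scores.
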