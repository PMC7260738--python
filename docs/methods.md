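# Methods

This note documents the statistical procedures, the synthetic-data
generative model, the defaults that matter, and the numerical conventions
used throughout the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort structure and QC

A cohort member carries a cancer-type code, age at diagnosis, sex, global
ancestry fractions over five groups (afr, eur, eas, sas, amr), the first
two genotype principal components, and a genotype-concordance QC metric.
Ancestry assignment is upstream of this package: fractions and PCs are
inputs, not inferred.

* **Admixture rule.** The consensus group is the largest-fraction
  ancestry; if the second-largest fraction exceeds 0.20 the sample is
  labelled `<primary>_admix`. For analysis, admixed samples merge into
  their primary group, so the analysis group is always one of the five
  base codes. Ties on the primary fraction break by the fixed code order
  afr, eur, eas, sas, amr (deterministic, logged).
* **Sample QC.** Concordance strictly below 0.60 drops the sample;
  exactly 0.60 is kept. Missing age or sex is preserved at load time and
  handled only where a model needs the covariate.
* **Variant QC.** All thresholds are literal boundary readings:
  caller consensus (SNVs: any of Varscan/GATK; indels: ≥ 2 of 3 callers,
  or Pindel-only at normal depth ≥ 30 and normal VAF ≥ 0.20), then
  normal-sample read support (alt reads ≥ 5 AND alt fraction ≥ 0.20 as
  one conjunctive rule) and rarity (every populated panel AF ≤ 0.0005;
  exactly 0.0005 is kept). A panel AF absent from the input is treated
  as 0 and flagged imputed — absence from a reference panel is evidence
  of rarity, so the filter errs toward keeping. Each dropped observation
  carries exactly one primary reason (coverage, alt depth, alt fraction,
  rarity — first failing rule in that order); the two filter stages are
  independent predicates, so their composition is order-independent.
  Tumor read support is deliberately not filtered on: tumor counts feed
  only the two-hit analysis.

## Pathogenicity scoring

Evidence tags arrive pre-assigned (the mapping from annotations to tags
is out of scope). The default points table has 12 pathogenic and 4 benign
modules: PVS1 +8 (truncation, dominant loss-of-function mechanism),
PSC1 +4 (recessive counterpart), PS1 +7 (same peptide change as an
established pathogenic variant), all other pathogenic modules +2, benign
modules −2. The +2 cap on unnamed pathogenic modules is enforced on any
user-supplied table; the benign magnitude is a package default (−2),
configurable, as only the cap structure — not the benign weights — is
pinned by the scoring scheme this implements. Classification:
reviewed-pathogenic ClinVar status ⇒ *pathogenic* regardless of score
(conflicting interpretations do not qualify); else score > 8 (strict) ⇒
*likely pathogenic*; else *uncertain*. Only pathogenic and likely
pathogenic variants ("predisposing") collapse to carriers.

## Association

Carriers form a boolean sample × gene matrix (two predisposing variants
of one gene in one sample are still one carrier). Within an ancestry,
cancer type c is tested against all other cancer cohorts of the same
ancestry as controls; controls never include c.

* **Logistic model.** case ~ carrier + age + sex + PC1 + PC2, maximum
  likelihood, Wald z test on the carrier coefficient; OR = exp(β),
  95% CI = exp(β ± 1.96·SE). Eligibility: ≥ 20 cases and ≥ 2 carriers in
  the ancestry cohort. Samples missing a required covariate are dropped
  at fit time with logged counts; single-sex cohorts drop the sex
  covariate to avoid collinearity. Separation (|β| > 10, a singular
  Hessian with one-sided carrier counts, or a perfect-separation error)
  is reported as a flagged result with an infinite or zero OR and no
  p-value — no penalized fallback, since plain Wald intervals are the
  reporting convention here.
* **Total Frequency Test.** Carriers are heterozygous, one pathogenic
  allele each; a group of N samples contributes 2N alleles. The 2×2 table
  (pathogenic vs remaining alleles, cases vs controls) is tested with the
  exact conditional hypergeometric test, one-sided toward case enrichment
  (two-sided by flag). The reference for the TFT describes the statistic
  only loosely; the exact conditional form is used because it is
  transparent and oracle-checkable. Eligibility: ≥ 20 cases, ≥ 1 carrier.
* **FDR.** Benjamini–Hochberg step-up, implemented directly
  (q(i) = min over j ≥ i of p(j)·m/j, capped at 1) and cross-checked in
  tests against both a naive oracle and statsmodels. The family is per
  ancestry (each ancestry's eligible cancer-gene pairs) by default —
  consistent with reporting test counts per ancestry — and can be made
  global.
* **Gene-level AF summaries** use Σ AC / max AN within each (gene,
  population) cell after an optional group-MAF < 0.5% rarity pre-filter;
  AN = 0 yields a missing frequency. PC variance shares are
  100·λᵢ/Σλ over the supplied leading eigenvalues.

## Two-hit analysis

LOH is tested per carrier variant with a two-sided exact conditional
(hypergeometric) test on [[tumor alt, tumor ref], [normal alt,
normal ref]]; the direction is the sign of tumor VAF − normal VAF.
BH-FDR is computed over all tested variants of a run (one family).
Categories: FDR < 0.05 toward the variant allele is significant LOH —
`loh_with_deletion` when external copy-number evidence marks wild-type
loss, else `other_loh`; non-significant results with FDR < 0.15 or tumor
VAF > 0.6 are `suggestive`. Both significant and suggestive calls require
the imbalance to point toward the variant allele: loss of the wild-type
copy is the second-hit mechanism under test, and a reference-ward shift
is not evidence for it. Copy-number evidence is an optional per-variant
input flag; the package does not call copy number. Biallelic events:
a carrier sample with ≥ 1 non-silent (non-synonymous) somatic mutation of
the same gene.

## Expression effects

Percentiles use the right-continuous ecdf (proportion of cohort values
≤ x) within the carrier's cancer cohort, the carrier's own sample
included; ties share percentiles. Extreme flags are strict: > 0.80 high,
< 0.20 low. ASE is the RNA VAF with a two-sided exact binomial test
against 0.5; zero RNA coverage yields missing values rather than an
error. Mis-splicing is cryptic/(consensus+cryptic) junction-spanning
reads. NMD competence uses the canonical 50-nt rule (escape if the
premature stop lies in the last exon or within 50 nt of the last
exon–exon junction); the boundary is exposed as a parameter since the
underlying classifiers differ in detail. The tumor-suppressor vs
oncogene comparison of carrier percentiles uses the two-sample KS test,
exact by exhaustive label permutation when n·m ≤ 100 (conditioning on
the observed values, so ties are handled naturally), asymptotic
otherwise.

## Synthetic cohort generator

The generator defines the study conditions for every recovery and
calibration test. Per (ancestry, cancer) cell of configurable size:
ages ~ Normal(60, 10) truncated to [20, 90]; sex ~ Bernoulli(0.5); a
configurable share (default 10%) of samples get a secondary ancestry
fraction above the 20% admixture threshold; PCs are drawn around
ancestry-specific centers (sd 0.01), which confounds ancestry with the
covariates and makes the regression's PC correction do real work; 2% of
samples are planted below the concordance cutoff and 2% lack an age, so
the QC and missing-data paths are exercised end to end.

Carrier status per (sample, gene) follows a logistic model: probability
expit(logit(baseline) + log(OR)) for the planted (ancestry, cancer,
gene) cell, the planted baseline elsewhere in that ancestry, and a
background frequency (default 0.002) otherwise. Carriers are
heterozygous with one pathogenic variant each — the rare-variant regime
(the collapsing step is still tested against multi-variant carriers in
unit tests). Read counts: depth ~ Poisson(60, floored at 10); normal
alt ~ Binomial(depth, 0.5); tumor alt ~ Binomial(depth, 0.5), or
Binomial(depth, 0.8) for the carriers (default probability 0.5) whose
tumor lost the wild-type allele. Mutant-allele loss is available behind
a flag but off by default — wild-type loss is the two-hit case of
interest. Somatic second hits (default probability 0.1) add a non-silent
mutation of the same gene; background somatic mutations include
synonymous ones. Expression is log-normal per gene; tumor-suppressor
carriers are multiplied by the suppression factor (default 0.3),
oncogene carriers by its inverse. RNA VAF is 0.1 (degraded allele) for
truncating variants without LOH, 0.8 under LOH, 0.5 otherwise; splice
variants also get junction read counts at a 28% mean mis-splicing
fraction. Decoy observations (common-AF or low-support variants with
weak evidence) are sprinkled in so that QC and classification have
something to reject. All draws come from one seeded generator; identical
seeds give identical outputs, and `emit_fixture` writes byte-identical
directories.

**What the generator does not emulate:** linkage disequilibrium and
haplotype structure, per-base sequence context, tumor purity/ploidy
variation, population-specific allele-frequency spectra, batch effects,
and annotation error. Passing recovery tests therefore demonstrates the
statistical machinery under its own assumptions, not robustness to these
real-data complications.

## Power and downsampling

Each power replicate draws `region_variants` (default 25, a proxy for a
5-kb region's rare-variant count) allele frequencies uniform below the
MAF bound, marks a causal fraction of them, draws genotypes binomially,
assigns case status by a logistic model with the log-OR applied per
causal allele, and runs the exact burden test on pooled rare alleles;
power is the rejection fraction at level alpha.

The default alpha is 0.05, a per-region test level. This choice was
calibrated once against three published power figures for the analogous
SKAT-based calculation (80% power at n = 1014 with OR 5; 67% at n = 811
with OR < 3; 36% at n = 180 with OR 9): under this generative model,
alpha = 0.05 reproduces the first anchor almost exactly (simulated power
0.82 at n ≈ 1000) and the right ordering and magnitude for the others,
while genome-wide levels (1e-3 to 1e-6) are inconsistent with all three.
Exact replication of SKAT's numbers is not promised — its haplotype pool
and variance-component statistic differ — so agreement is expected at
the order-of-magnitude level only.

The downsampling analysis subsamples cases of one (ancestry, cancer)
cohort uniformly without replacement at each requested size (controls
kept in full), reruns the association, and counts genes significant at
FDR < 0.05, reporting the per-size mean and range over iterations
(default 10). Per-size means replace presentation-only curve smoothing.

## Numerical conventions and test-scale choices

* Coordinates are 1-based (VCF convention); variant identity is
  `chrom:pos:ref:alt`.
* Writers emit deterministic TSV: declaration column order, rows sorted
  by (ancestry, cancer, gene, ids), floats at 6 significant digits.
* Exact tests delegate to scipy (`fisher_exact`, `binomtest`,
  hypergeometric machinery); every exact p-value path is verified in the
  test suite against an independent enumeration or closed-form tail
  oracle on small tables, and BH against a naive step-up oracle.
* Monte-Carlo test scales are chosen to keep the default suite fast while
  leaving binomial error well inside the asserted margins: 2000
  replicates for null calibration of the burden test, 50 seeded cohorts
  (~1000 samples each) for association recovery, 150–400 replicates per
  power design point. The null-calibration cohort uses 1000 cases vs
  3000 controls at collapsed carrier frequency 0.1: the exact conditional
  test is conservative by construction, and at sparser counts its
  discreteness keeps the realized size well below the nominal level
  (pre-test size scans gave 0.031–0.042 for balanced designs at carrier
  frequencies 0.02–0.1, versus 0.0475 for this design), so a near-nominal
  calibration check is only meaningful where the null distribution is
  dense.
* The bundled gene table (`cpg/data/cpg_genes.tsv`) is a synthetic
  curated list of 30 well-known predisposition genes with tumor-
  suppressor/oncogene roles, standing in for a user-supplied curated
  panel; every entry point accepts an external list.

## Known limitations

* Evidence-tag assignment (the mapping from functional annotation to
  PVS1-style tags) is out of scope; garbage tags in, garbage classes out.
* The logistic fit reports separation rather than falling back to
  penalized likelihood; sparse cells are better served by the exact TFT.
* The LOH test treats read counts as exact binomial draws; it does not
  model tumor purity, subclonality or copy-number state beyond the
  optional deletion flag.
* The power model's uniform-MAF, per-allele-OR parameterization is a
  deliberate simplification; it is stated fully here precisely because
  the SKAT internals it stands in for are not restated in this package.
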