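# Methods

This note documents the statistical model behind `amygrs`, the synthetic
data it is tested on, the numerical choices, and the limits of what the
test suite demonstrates.

## 1. The four-phase score-building procedure

**Discovery GWAS.** For each discovery cohort and variant *j*, the
quantitative phenotype is regressed on dosage with covariates age, sex and
the first *k* = 5 genetic principal components:

&nbsp;&nbsp;y = α + β_j x_j + γᵀc + ε.

Missingness is handled per variant by complete-case analysis (the PLINK
convention): samples missing x_j are dropped for variant *j* only. The scan
is implemented by computing the covariate cross-products once and
*downdating* them for each variant's missing rows, then solving one small
batched normal-equations system per variant. This is algebraically
identical to refitting the full design per variant; the equivalence against
an independent pseudoinverse oracle (to 1e-8) is part of the test suite.
p-values come from the t distribution on the residual degrees of freedom.

**Principal components** are the top eigenvectors of the genetic
relationship matrix of mean-imputed, per-variant standardized dosages —
an exact eigendecomposition, not a randomized solver, so runs are
bit-reproducible. Zero-variance variants are excluded with a warning. The
sign convention (largest-magnitude loading positive) makes components
comparable across runs. PCs are computed once per cohort on QC-passed
dosages without prior LD pruning; pruning can be emulated by passing a
thinned dataset.

**Meta-analysis** pools the per-cohort summaries with the
DerSimonian–Laird moment estimator: fixed weights w_i = 1/se_i²,
heterogeneity Q = Σ w_i (β_i − β_fixed)², τ² = max(0, (Q − (k−1)) /
(Σw − Σw²/Σw)), random-effects weights 1/(se_i² + τ²), normal two-sided
p-values. Variants observed in a single cohort are kept with k = 1 and τ²
= 0 rather than dropped (dropping would silently shrink the candidate
pool; the per-study direction string records availability). Effect alleles
are harmonized to the first cohort before pooling: swapped allele pairs
flip the beta and complement the frequency; irreconcilable pairs are
dropped and counted.

**Candidate selection and refinement.** Candidates are variants with
meta-analytic p strictly below 5e-5. Each candidate is re-tested in the
independent neuropathology cohort (same covariate model, quantitative
amyloid outcome); it survives only with two-sided p strictly below 0.2
*and* a concordant direction. Both inequalities are strict, mirroring an
exclusion rule phrased as "p ≥ 0.2". Under a null replication cohort the
two clauses retain 0.2 × 0.5 = 10% of candidates — a property the
acceptance suite verifies to ±1%. Every candidate receives a decision
record attributed to the first failing clause (missing → p → sign), so the
decision table partitions the candidate list.

**Clumping and scoring.** Greedy LD clumping takes the best remaining
candidate by (p, position) and discards candidates on the same chromosome
within 250 kb with r² ≥ 0.1 against it (r² = squared dosage correlation on
jointly non-missing samples of the pooled discovery panel). The 250 kb
window is the common tool default; only the r² cutoff is prescribed by the
study design, so the window is config-exposed. The score is the weighted
dosage sum with weights equal to the meta-analytic betas, divided by the
number of model variants used (mean-per-variant convention; a raw-sum
switch exists — the choice affects scale, not p-values). Missing dosages
are imputed as 2 × the *scoring* cohort's allele frequency, never the
discovery frequency, to avoid leaking discovery information. Alleles are
harmonized by matching effect/other pairs; a swapped pair contributes
2 − dosage, which leaves the score invariant to allele-label flips.

**Evaluation.** Quantitative outcomes: OLS with covariates, reporting the
score beta, SE, t-based 95% CI, and incremental variance explained ΔR² =
R²(covariates + score) − R²(covariates). Binary outcomes (high Braak
stage): logistic regression reporting odds ratio with Wald 95% CI; no
pseudo-R² is computed because no single convention is standard.

## 2. Quality control

Variant filters, in documented order (first failing filter is charged):
call rate < 0.95 → exact Hardy-Weinberg p < 1e-5 → minor allele frequency
below the 5% analysis floor (an 1% array-level floor is also represented
in the threshold set). The HWE test is the exact conditional test — the sum
of probabilities of all heterozygote counts at most as probable as the one
observed, given the allele counts — computed from a cached log-factorial
table; a full-enumeration oracle check over every table with N ≤ 200 is in
the acceptance suite. HWE and relatedness use hard calls (fractional
dosages rounded); association keeps fractional values.

Sample filters: call rate < 0.98, then relatedness. PI_HAT = P(IBD=1)/2 +
P(IBD=2) by the method-of-moments decomposition of identity-by-state
counts with allele frequencies estimated from the full sample, clamped to
[0, 1]. PLINK's small-sample bias-correction factors are omitted; at the
sample sizes involved the bias is negligible against the 0.25 decision
threshold (duplicate ≈ 1, parent-offspring ≈ 0.5, unrelated ≈ 0, verified
by pedigree simulation). For each flagged pair the member with the lower
call rate is removed (tie: the later sample). Pipeline-level screening
computes all-pairs PI_HAT via indicator-matrix products on an evenly
spaced subset of 5,000 variants — a screening estimate whose Monte-Carlo
error (SE ≈ 0.01) is far below the threshold; the per-pair API uses every
shared variant and requires at least 500.

Genomic inflation: λ = median(χ²₁ quantiles of the p-values) / 0.45494.

## 3. The synthetic study

The generator emulates the *structure* of a multi-cohort amyloid
endophenotype study: two discovery cohorts (983 and 513 samples,
Centiloid-like quantitative outcome), one neuropathology cohort (710;
percent-area-like amyloid, tangle density, binary high-Braak indicator at
the 0.8 quantile of tangle burden), and one plasma validation cohort (641;
pg/mL-like outcome).

**Genotypes.** Haplotypes arise from a latent-Gaussian threshold model:
within each 20-variant LD block the latent vector has AR(1) correlation
ρ = 0.7; an allele is carried when the latent value falls below the
allele-frequency quantile; a dosage is the sum of two independent
haplotypes. This preserves Hardy-Weinberg equilibrium within each ancestry
stratum exactly and gives controllable adjacent-variant r² (validated
against numeric integration of the bivariate-normal orthant probability).
Base allele frequencies are uniform on [0.05, 0.5]; with ≥ 2 ancestry
strata, per-stratum frequencies follow a Balding–Nichols Beta distribution
with Fst = 0.01 (a single stratum uses the base frequencies unchanged —
there is nothing to diverge from). Blocks sit 1 Mb apart along 22
chromosomes with 5 kb within-block spacing, so distinct blocks never share
a clumping window. Missingness is completely at random at rate 0.002.

**Phenotypes.** Eight causal variants occupy eight distinct, randomly
chosen blocks (never adjacent by construction, and always above the 5% MAF
floor). On the standardized scale,

&nbsp;&nbsp;y = Σ_j a·β_j·x_j + β_age(age − mean age) + β_sex·sex + stratum
offset + ε,

where *a* is the cohort's attenuation multiplier and Var(ε) is set so the
causal fraction of the genetic-plus-noise variance equals h² a². The
result is mapped to the modality's reporting units by a fixed affine
transform, which leaves every association statistic invariant. Defaults:
h² = 0.24 split equally (3% per causal variant — at 1.5–2% the compounded
selection, DerSimonian–Laird k = 2 τ²-noise penalty, and refinement
filters leave well under 6 of 8 blocks recoverable on average, i.e. no
choice in that range exercises the recovery property meaningfully);
attenuation 1.0 for discovery, 0.7 for neuropathology, 0.6 for plasma
(planted validation score-explainable variance 0.24 × 0.6² ≈ 8.6%, of
which a realized 6-variant score typically captures ~6%); tangle
attenuation 0.5; β_age = 0.01/yr, β_sex = 0.15 (small but nonzero, so the
covariate adjustment is exercised); sex ~ Bernoulli(0.5) independent of
genotype; age ~ N(74, 9²).

The per-cohort phenotype noise structure and covariate effect sizes of any
real cohort are unknown to us; these defaults are free parameters of the
simulation, not estimates of any study's data.

**What the generator does not model:** imputation uncertainty, strand
flips, multi-allelic sites, the X chromosome, informative missingness,
batch effects, assay-specific noise, or *APOE* genotype itself (the design
assumes an ε3/ε3-restricted analysis population). Passing tests therefore
demonstrate the pipeline's statistical behaviour under its own
assumptions, not performance on real arrays.

**Truth bookkeeping.** Datasets carry the causal ids, betas, block map and
theoretical dosage variances, so tests can count recovered causal blocks
and compute the planted score-explainable variance of a *realized* score
as corr(score, true genetic value)² × planted causal fraction — the
quantity the measured ΔR² is compared against.

## 4. Numerical choices and degenerate inputs

- Reproducibility: every random draw descends from one `SeedSequence`;
  the variant-level model is a function of the seed alone, so all cohorts
  of a study share variants, frequencies and truth.
- HWE ties: tables with conditional probability equal to the observed one
  (up to a 1e-9 relative tolerance) are included in the tail sum.
- Strict inequalities at both selection thresholds (p < 5e-5, p < 0.2).
- Clumping ties on p are broken by smaller genomic position, making the
  greedy result deterministic and equal to the unique dominance-consistent
  subset (verified against exhaustive subset enumeration up to 12
  candidates).
- Zero-variance dosages are skipped with a warning in GWAS, excluded from
  PCs, and raise in `ld_r2`.
- Logistic fits flag (quasi-)separation and non-convergence per variant
  (|β| > 25 or SE > 100 or optimizer failure) and carry no estimate.
- Collinear covariates raise an error naming the offending column.
- `meta_analyze` with k = 1 sets Q = 0, τ² = 0 rather than 0/0.
- Empty candidate sets propagate as empty models with a diagnostic of
  where the funnel emptied; the pipeline reports partial funnels rather
  than fabricating a score.

## 5. Problem sizes used in the test and acceptance runs

Unit tests run on cohorts of 50–10,000 samples and up to 20,000 variants,
chosen so each statistical tolerance (binomial or Monte-Carlo SE) is a
few times tighter than the asserted band. The end-to-end recovery check
uses the emulated study's cohort sizes (983/513/710/641) with m = 20,000
and 10 seeds; the acceptance script repeats it with 5 seeds. The
null-safety check runs 40 small null pipelines (n = 200–300, m = 2,000)
with a relaxed candidate threshold (p < 0.01): at the production threshold
a null run almost never yields a non-empty model, leaving no validation
p-values to test for uniformity, and the leakage property being tested is
threshold-independent.

## 6. Known limitations

- The refinement step's selection-on-replication means in-sample ΔR²
  estimates are optimistic; only the held-out plasma cohort gives an
  unbiased read — the same caveat applies to the design it implements.
- DerSimonian–Laird with k = 2 cohorts is noisy in τ²; it costs real
  selection power at suggestive thresholds (quantified in the test suite)
  but is retained as the field-standard random-effects choice. A
  fixed-effect mode exists as a configuration flag for comparison.
- PI_HAT without LD pruning can be mildly biased on strongly structured
  panels; with two strata at Fst ≈ 0.01 the effect is negligible.
- The clumping LD panel is the pooled discovery genotype set; no external
  reference panel is supported.
- No mixed-model association, rare-variant tests, X-chromosome dosage
  model, multi-threshold score search, or shrinkage-based (LDpred-style)
  weighting.
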