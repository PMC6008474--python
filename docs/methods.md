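# Methods

This note records the models, conventions and numerical choices behind
`repromr`, and what the synthetic-data generator does and does not emulate.

## Instruments and curation

An instrument is one SNP with a per-allele effect on exposure age (`beta`,
years), its SE and GWAS p-value. All single-trait records are harmonised so
the stored effect allele is the trait-increasing one (`beta >= 0`);
harmonisation is idempotent (flip alleles, complement the frequency, negate
the beta).

Curation runs in the order sex-chromosome removal → proxy substitution →
correlation pruning. Proxy substitution precedes pruning because a
substituted proxy can itself be a member of a correlated pair; the order
matches the narrative order in which published instrument lists are
processed. Proxies must exceed r² = 0.8 with the missing variant; the best
candidate is taken, inheriting the original beta/SE/p (it tags the same
signal) and re-harmonised. A record with no qualifying proxy is dropped and
logged — never an error, since partial instrument loss is the expected
outcome.

Pruning removes, for every pair with r² > 0.01, the member with the higher
exposure p-value, iterating until no pair offends. The iteration always
deletes the globally weakest offender first and breaks p-value ties toward
the lexicographically larger rsid, making the surviving set independent of
input order (verified by a brute-force pairwise-enumeration oracle on small
sets and by permutation tests on the full fixture).

Genotype QC removes SNP columns with call rate below 0.98, minor allele
frequency at or below 0.01, or Hardy–Weinberg goodness-of-fit p below 1e-4.
HWE is tested in controls only, on dosages hard-called to the nearest
genotype (a 1-df chi-square on the three genotype counts): dosages are
continuous, but the HWE null concerns genotype frequencies.

Palindromic (A/T, C/G) records with allele frequency in [0.4, 0.6] are
flagged but kept by default (`drop_palindromic` switches to dropping);
flagging preserves the published instrument counts while leaving strand
ambiguity visible to the analyst.

### The lifetime-exposure set

For the combined score, menarche records are re-oriented to the
trait-*decreasing* allele with the beta kept positive: each copy of the
(new) effect allele shortens menarche age by `beta` years and therefore
lengthens the oestrogen-exposure window by `beta` years. Because dosage
columns are coded on the trait-increasing allele, such records carry a flag
instructing the scoring step to use the complemented dose `2 − G`. Both
members of any cross-trait pair with r² > 0.01 are removed: the two traits'
p-values are not comparable, so neither member can claim precedence.

## Risk scores and year-scaling

The raw score is the plain weighted dose sum — not divided by the SNP
count. Missing doses are mean-imputed per SNP from controls (unbiased under
missing-at-random; a strict mode rejects incomplete input instead).

Scaling divides the raw score by the slope of an OLS regression of the raw
score on self-reported exposure age in calibration controls, fitted per
study (at least 30 usable pairs each; zero-age-variance studies are
excluded with a warning) and pooled by inverse-variance fixed effects. When
no calibration data are supplied the published defaults apply: 0.57
(menarche), 0.98 (menopause). Scaling is a pure reparameterisation: the
logistic coefficient on the scaled score equals the raw-score coefficient
times the scaling slope, an identity the suite checks to 1e-8.

## One-sample MR

Case status is regressed on the scaled score by maximum-likelihood logistic
regression (statsmodels Newton IRLS, relative tolerance 1e-8, at most 100
iterations), adjusted for age, study indicators and principal components of
genetic ancestry — 3 PCs for the GECCO-style consortium, 10 for the
CORECT-style one, configurable per study group. Per-consortium estimates
are pooled by fixed-effects meta-analysis
(`beta = Σ b_i/se_i² / Σ 1/se_i²`, `se = (Σ 1/se_i²)^{-1/2}`).
Non-convergence or separation raises an explicit error; there is no silent
fallback. Confidence intervals use the normal 1.96 multiplier throughout —
the target sample sizes are in the tens of thousands. Missing covariates
are handled complete-case within each model, so stratified analyses report
reduced ns.

Stratified analyses refit per stratum level and test effect heterogeneity
by a likelihood-ratio test comparing the pooled model with and without
score-by-stratum interaction terms (chi-square, levels − 1 df); individuals
with a missing stratum value are excluded, and a single-level stratum is
flagged undefined rather than raised. Colon-vs-rectum heterogeneity uses
the case-only design: logistic regression of tumour site on the score among
cases, adjusted like the main model, reporting the Wald p of the score
term. Sensitivity variants enter a 77-SNP BMI risk score as an additional
linear term, or rebuild the score on the instrument subset not associated
with BMI.

## Two-sample MR

Per-SNP Wald ratios are `beta_outcome/beta_exposure` with first-order
delta-method SE `se_outcome/|beta_exposure|`; zero-exposure-beta rows are
dropped with a warning. IVW is the zero-intercept weighted regression of
outcome on exposure betas with weights `1/se_outcome²` — algebraically the
precision-weighted mean of ratios, which the tests verify against an
independent brute-force computation to 1e-10. MR-Egger frees the intercept;
exposure betas are oriented non-negative first (Egger is not
orientation-invariant). Both estimators take the stated outcome variances
as known (scale fixed at 1, no multiplicative over-dispersion adjustment),
so their SEs come straight from `(XᵀWX)^{-1}`.

The weighted median orders ratios, accumulates normalised inverse-variance
weights, and interpolates at cumulative weight 0.5 with SNP *j* placed at
position `S_j − w_j/2`. Tied ratios are merged (weights summed) before
interpolation, which makes the estimate a function of the weighted
empirical distribution only — duplicating every SNP is then an exact no-op
— while leaving the generic distinct-ratio case identical to the standard
interpolation. The SE is a parametric bootstrap (default 10,000 replicates;
fewer than 100 is rejected as unstable): both beta columns are resampled
from normals at their stated SEs, the estimator recomputed, and the SD
taken. The bootstrap is vectorised and bit-reproducible under a fixed seed.

Funnel data pairs each ratio with its precision `1/se_ratio` and attaches
an Egger-type asymmetry test: a weighted regression of ratio on its SE
(weights = precision²), whose slope drifts from zero when imprecise
instruments deviate systematically — the funnel signature of directional
pleiotropy.

## Diagnostics and power

The instrument-strength F-statistic is `R²(n−K−1)/((1−R²)K)`. The score is
treated as a single instrument (K = 1) with *n* the analysis sample size;
this is the convention under which the statistic describes the fitted
score-on-exposure regression, and the conventional F > 10 rule applies. The
confounder screen regresses each risk factor on the score among controls —
linear for continuous factors, logistic for binary, multinomial (LR test)
for multi-level — reporting raw p-values without multiplicity correction.

Analytic power for the two-sided score Wald test on a binary outcome uses
the normal approximation

```
power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2}),   λ = |log OR_per_SD| · √(N · R² · φ(1−φ))
```

with φ the case fraction; at OR = 1 this reduces exactly to α. The
simulation mode draws replicate cohorts at the exact case/control counts —
a standardised exposure whose genetic score explains R² of its variance,
disease assigned by the logistic model, cases and controls sampled
retrospectively — and reports the Wald rejection fraction. The two modes
agree within Monte-Carlo error (±3 points at 2,000 replicates, asserted in
the suite at a smaller design). The simulation's inner logistic fit is a
dedicated two-parameter Newton solver returning the identical MLE and
observed-information SE as a generic GLM routine; it exists purely to keep
2,000 replicate fits of N ≈ 24,000 fast.

## The synthetic-data generator

The generator emulates the statistical structure of a retrospective
case-control MR study; its defaults are the study conditions: 12,944 cases,
10,741 controls, 358 instruments, explained variance R² = 0.069 (menarche;
0.057 and SD 4.8 y for menopause), exposure SD 1.5 y, 4 studies split
across two consortia.

* **Manifests** carry the curation hazards of a published hit list in
  controlled numbers: sex-chromosome variants, panel-missing variants with
  strong proxies (r² in [0.83, 1.0]) or only sub-threshold candidates,
  correlated pairs, BMI-associated subsets. Betas are scaled so the
  post-curation score variance equals `R² · SD²` — the genetic variance a
  cohort calibrated at R² needs.
* **Dosages** are Hardy–Weinberg hard genotypes shrunk toward the panel
  frequency with per-SNP quality in [0.9, 1], mimicking the 0.97–0.98 mean
  imputation quality of well-imputed variants. No LD structure exists
  beyond the flagged pairs, and no haplotypes are simulated.
* **Exposure** is `baseline + genetic score + confounder path + residual`,
  the residual variance set from the empirical score variance so the true
  GRS explains exactly the target R² (±0.01 at n ≥ 20,000, asserted); an
  unreachable target (e.g. a confounder path wider than the residual
  budget) raises a calibration error.
* **BMI** can correlate with the score (`bmi_pleiotropy_r`), emulating
  instruments acting partly through adiposity, and/or be driven by its own
  SNP set; it feeds exposure and disease through `confounder_spec`.
* **Disease** follows a logistic model on exposure (chosen log-OR per
  year), the confounder, and optional direct per-allele SNP effects
  (fraction, mean, SD — mean 0 for balanced, nonzero for directional
  pleiotropy). The intercept is solved (Brent) so the oversampled
  population yields the case fraction, and cases/controls are drawn without
  replacement to *exact* counts — logistic odds ratios are invariant to
  outcome-dependent sampling, which the recovery and coverage tests
  confirm (93–97% CI coverage over 200 replicates).
* **Covariates** (age, study labels, synthetic PCs as standard normals
  uncorrelated with genotype, MHT use, menopausal status, tumour site,
  smoking, aspirin use, family history, education) are populated with
  plausible marginals; population structure itself is out of scope, PCs
  exist only as adjustment covariates.

Every stochastic operation takes an explicit seed and uses its own
generator; no global state. With the seed fixed, all outputs are
bit-reproducible, and the pipeline's report bundle is byte-identical across
reruns.

What passing tests do **not** show about real data: the generator has no
linkage disequilibrium beyond flagged pairs, no population stratification,
no genotyping batch effects, no differential misreporting of exposure ages,
and its covariates are independent of genotype by construction. Results on
real consortium data additionally depend on harmonisation and imputation
quality that the generator only caricatures.

## Problem sizes used in the checked results

The suite's distributional checks use sizes chosen to make Monte-Carlo
error small relative to the asserted bands while keeping the default run
short: 200 replicate cohorts of 2,000/2,000 for recovery and coverage, 500
summary-statistic tables of 50 SNPs for the Egger-intercept calibration and
power and for the weighted-median robustness comparison, and 2,000
replicate cohorts at the full 23,685-individual design for the power
simulation. The acceptance script uses the full study design throughout.

## Known limitations

* No random-effects meta-analysis, MR-PRESSO, mode-based or multivariable
  MR, and no LD-aware IVW for correlated instruments.
* The weighted-median bootstrap is parametric only.
* LD is consumed as an input (tables of pairwise r²); the package never
  computes it from reference panels.
* The case-only site test and stratified analyses assume the strata
  partition individuals; overlapping strata are not supported.
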