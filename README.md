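# repromr

Mendelian randomisation (MR) of reproductive-timing genetic risk scores on
colorectal-cancer (CRC) risk, as a tested, reusable Python pipeline.

## The scientific problem

Observational studies disagree on whether endogenous oestrogen exposure —
bracketed by age at menarche and age at natural menopause — affects a
woman's risk of colorectal cancer. Self-reported exposure ages suffer from
recall bias and confounding (childhood BMI both advances menarche and raises
CRC risk). MR sidesteps these problems by using germline variants as
instrumental variables: alleles are randomised at conception, so a genetic
proxy for the exposure is immune to recall error and, if the instrument
assumptions hold, to confounding and reverse causation.

`repromr` implements the full analysis around a **weighted genetic risk
score (GRS)** instrument,

```
GRS_k = Σ_n β_n · G_kn
```

the sum over instrument SNPs of imputed allele doses `G ∈ [0, 2]` weighted
by the published per-allele effect `β` (years of exposure age per allele).
Dividing the score by the slope of a regression of GRS on self-reported age
in calibration controls (0.57 for menarche, 0.98 for menopause) converts it
to year units, so a logistic odds ratio on the scaled score reads as the
change in CRC risk *per year* of exposure age. A combined score — menarche
alleles counted on the age-*decreasing* allele plus menopause alleles on the
age-*increasing* allele — proxies the total lifetime oestrogen-exposure
window.

The package covers:

* **instrument curation** — proxy substitution (r² > 0.8), correlation
  pruning (r² > 0.01, dropping the weaker association), allele
  harmonisation, genotype QC (call rate, Hardy–Weinberg in controls, MAF),
  BMI-restricted subsets, and the combined lifetime set;
* **one-sample MR** — covariate-adjusted logistic regression of case status
  on the scaled score, per-consortium fits pooled by fixed-effects
  meta-analysis, stratified analyses with likelihood-ratio heterogeneity
  tests, case-only colon-vs-rectum heterogeneity, BMI-GRS adjustment;
* **two-sample MR** — per-SNP Wald ratios, IVW, MR-Egger (slope and
  directional-pleiotropy intercept test), weighted median with
  parametric-bootstrap SEs, funnel-plot data with an asymmetry test;
* **diagnostics & power** — instrument F-statistic `R²(n−K−1)/((1−R²)K)`,
  a confounder screen among controls, and analytic + simulation power for
  the GRS Wald test;
* **synthetic data** — a generator producing instrument manifests, dosage
  matrices, case-control cohorts and summary-statistics tables with the
  statistical structure the analysis assumes (calibrated explained
  variance, confounding and pleiotropy paths, exact retrospective
  case/control counts), so every stage is testable without restricted
  consortium data.

## Worked example

```python
import math
from repromr import (
    SimulationSpec, generate_manifest, generate_cohort, generate_summary_stats,
    curate, compute_grs, scale_grs, fit_grs_logistic,
    ivw, egger, weighted_median, f_statistic, mr_power, PowerSpec,
)
from repromr.synthdata import derive_proxy_table, derive_ld_matrix

# a published-list-sized manifest: 389 variants, 12 on sex chromosomes,
# 42 missing from the panel (7 without a usable proxy), 12 correlated pairs
manifest = generate_manifest(389, n_sex_chr=12, n_missing=42, n_no_proxy=7,
                             n_correlated=12, seed=1)
instruments, log = curate(manifest, derive_proxy_table(manifest, seed=2),
                          derive_ld_matrix(manifest))

spec = SimulationSpec(n_cases=4000, n_controls=4000,
                      causal_logor_per_year=math.log(0.90), seed=3)
dataset = generate_cohort(spec, instruments)
score = scale_grs(compute_grs(dataset.dosages, instruments), 1.0)
est = fit_grs_logistic(dataset.cohort, score)

stats = generate_summary_stats(instruments, spec, seed=4, se_outcome=0.02)
```

Output:

```
curation: 389 published variants -> 358 instruments
one-sample MR: OR/year 0.910 (95% CI 0.809-1.024), p 0.116
two-sample IVW: OR/year 0.947 (0.893-1.005)
two-sample MR-Egger: OR/year 0.930 (0.842-1.029)
two-sample weighted median: OR/year 0.958 (0.875-1.048)
Egger intercept 0.0008 (p 0.67)
F-statistic: 1755
power, OR 0.85/SD: 0.91
```

The curation log accounts for every exclusion (12 sex-chromosome, 7 without
a proxy, 12 correlated), leaving 358 instruments. The one-sample estimate
recovers the simulated protective effect (true OR 0.90/year) within its
confidence interval; the three two-sample estimators agree, and the Egger
intercept near zero correctly reports the absence of directional pleiotropy
in this simulation. The F-statistic of the score at the study sample size
(n = 23,685, explained variance R² = 0.069, K = 1 instrument) is 1755 —
far above the conventional weak-instrument threshold of 10.

A command-line interface mirrors the library
(`repromr simulate | curate | grs | mr1s | mr2s | validate | power | run`);
`repromr run --config run.yaml --out report/` executes the whole pipeline
and writes Table-style TSV results, diagnostics JSON, funnel data and a
run manifest with input hashes and the seed.

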