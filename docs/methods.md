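# Methods

This note documents the statistical model implemented by `riskmom`, the
synthetic study conditions under which the package is exercised, and the
numerical and design choices made where more than one reasonable option
existed.

## Model

### MoM standardisation

For each marker the median concentration of unaffected men is modelled as

    log10 median(age) = b0 + b1·age + b2·age²

fitted by ordinary least squares of log₁₀ concentration on age (and age²).
Under the log-Gaussian assumption the mean of the logs equals the log of
the median, so the OLS prediction is the log median; this realises median
regression without quantile machinery. In `auto` mode the quadratic term
is retained iff its partial F-test p-value falls below `alpha`
(default 0.05). A MoM is the concentration divided by the predicted
median at the man's age. Ages outside the fitted range extrapolate with a
warning flag rather than an error, because screening ages (55+) can
exceed the age range of an archival cohort whose median age at sampling
is in the mid-50s. MoM values are scale-equivariant: a multiplicative
assay or storage effect applied to all samples cancels exactly when the
median curve is refitted, which is the reason the method tolerates decades
of sample storage.

BMI adjustment is a log-linear correction, `mom / 10^(slope·(BMI − ref))`,
with the reference BMI defaulting to the cohort median so the adjustment
is neutral for a typical man. It is provided because marker levels fall
modestly with BMI, but it is not part of the default pipeline: the risk
model's performance is essentially unchanged with or without it.

### Group distributions

Within each group (affected / unaffected) and follow-up window (≤5y, <10y,
all), log₁₀ MoM panels are modelled as multivariate Gaussian: per-marker
means and SDs (casewise deletion), pairwise-complete Pearson correlations
projected to the nearest positive semi-definite matrix by eigenvalue
clipping at 1e−8 (pairwise correlations need not be jointly PSD; on
well-conditioned inputs the projection moves entries by far less than
0.05). A Gaussian quantile-correlation statistic (`qq_fit_statistic`)
quantifies adequacy of the log-Gaussian fit.

Truncation limits default to the 1st/99th percentiles of the *unaffected*
fitted distribution per marker and are shared by both groups; parameter
files may override them with published values. Truncation is applied to
the input point before density evaluation (the convention of prenatal
multi-marker screening), not to the densities' normalising constants, so
the likelihood ratio is continuous, capped, and constant beyond the
limits.

### Risk

The prior over a horizon of `t` years sums the (linearly interpolated)
annual incidence at ages a, a+1, …; the `exp-cumulative` alternative
1 − exp(−Σ) is available but differs negligibly at prostate-cancer rates,
so `sum` is the default. Posterior odds are prior odds times the LR, a
screen positive is risk ≥ cut-off with ties positive, and risks display
as "1 in N" with N rounded to the nearest integer.

### Performance estimation

`simulate_performance` draws, per group, an age from the group-specific
age distribution (affected weight ∝ population weight × prior, unaffected
∝ weight × (1 − prior)) and a log-MoM panel from the group Gaussian,
computes each subject's risk, and reports DR and FPR with binomial
Monte-Carlo standard errors. The default screened population is uniform
over ages 55–74 in 1-year steps — screening from 55 is reasonable because
affected men below that age are rare, and 74 is a trial-like upper bound —
and every age-dependent result logs this setting. Overall prevalence for
the OAPR is the weighted mean prior of the same population model, so the
OAPR identity `x = ((1 − prev)·FPR)/(prev·DR)` holds exactly by
construction.

Fixed-DR (or fixed-FPR) operating points take the implied cut-off as the
empirical (100 − target) percentile of the fixed group's simulated risks —
exact in the simulation's own terms, with ties at the cut-off positive,
matching classification.

`quadrature_performance` is the deterministic oracle for 1–2 marker
panels. Since the posterior risk is monotone in the LR, the
screen-positive region at age a is {LR ≥ t(a)} with t(a) the cut-off odds
divided by the prior odds; the LR is evaluated once on a cell grid
(default 2001 cells per marker spanning ±8 SD of both groups) and each
cell contributes its exact Gaussian probability mass — CDF increments in
1-D, marginal × conditional CDF increments in 2-D — so the discretisation
error is confined to cells straddling the region boundary and is far
below Monte-Carlo error at the simulation sizes used.

Mass-unit (ng/ml threshold) performance is closed-form when single-marker
parameters on the log₁₀ ng/ml scale are supplied, and otherwise
reconstructs concentrations as MoM × age-specific median with age drawn
from the population model.

Bootstrap CIs resample the **matched set** (one case plus its controls)
with replacement, preserving the matched design, refit the entire
pipeline (median curves, group parameters, performance) per replicate,
and report 2.5th/97.5th percentiles over 500 replicates by default. A
replicate failure rate above 10% aborts with a diagnostic.

The once-only analysis counts, per follow-up band, affected men whose
risk is at or below a very low cut-off (default 1 in 5000 — cases that a
"test once, then stop" policy would miss) and unaffected men below it
(screening examinations avoided).

## Synthetic study conditions

The package ships no measured data. `riskmom.defaults` defines a
synthetic reference parameter set with the summary structure of an
archival matched case-control cohort:

- unaffected median MoM 1 for every marker; log₁₀ MoM SDs 0.33/0.31/0.33/
  0.28/0.21 for total/free/intact PSA, hK2, MSP (IQR-scale spreads typical
  of these assays);
- affected median total-PSA MoM 14.4 in the 0–5-year follow-up band,
  declining to 3.7, 2.4, 1.7 and 1.4 in later bands; other markers scale
  log-proportionally from their short-follow-up medians (free PSA 6.0,
  intact PSA 7.2, hK2 3.2); MSP fixed at 1 (no discrimination);
- PSA forms correlated ~0.9 pairwise, hK2 ~0.3 with each PSA form, MSP
  near zero — hK2's relative independence from PSA is what makes it a
  useful second marker despite being weak alone;
- a national-registry-style annual incidence curve rising from ~1.2/1000
  at 55 to ~7.8/1000 at 80;
- cohort structure: 571 cases, 4:1 matched controls, age at sampling
  truncated-normal (median 54, IQR 49–59), follow-up band probabilities
  0.021/0.060/0.13/0.24/0.55, death-cause labels assigned with
  probability 324/571 independent of marker values (so died-of and
  died-with subgroups are exchangeable), optional uniform per-assay
  missingness.

The generator reproduces the correlation structure, the follow-up decline
and the matched design, but not features of real data such as non-Gaussian
tails, assay floor/ceiling effects, age-dependent marker variance, or
informative missingness. Passing tests therefore demonstrate the internal
consistency and calibration of the pipeline — not the field performance
of any marker panel. The default parameters are illustrative; real use
requires parameter files estimated from a real cohort and a current
incidence table.

## Problem sizes and tolerances

Monte-Carlo performance runs use 2×10⁵ draws per group (rates then carry
standard errors ≲0.07 percentage points near FPR 3%); oracle-agreement
checks assert within 3 binomial SEs. End-to-end recovery uses a 500-case
single-band cohort, where parameter-estimation error dominates (≈0.8
points SE on DR, ≈0.3 on FPR); the test bound is ~4 combined SEs.
Bootstrap calibration runs 50 outer cohorts × 200 inner replicates with a
single-marker quadrature estimator and requires 90–98% coverage of the
generating model's DR. The acceptance script uses the same sizes with 500
bootstrap replicates.

## Known limitations

- Only baseline (single time-point) marker measurements are modelled; no
  serial-change covariance.
- The prior ignores competing mortality and non-age risk modifiers
  (family history, genetics).
- Quadrature supports at most 2 markers; larger panels rely on Monte
  Carlo alone.
- The once-only analysis treats follow-up bands as categorical; no
  survival-time modelling.
- Mass-unit comparisons depend on the assumed median curves and screened
  age distribution; results report that setting and the acceptance script
  includes a fixed-age sensitivity entry.
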