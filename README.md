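# fshthreshold

Threshold-effect (segmented dose–response) analysis for cycle-level IVF
cohorts: does the relationship between mid-stimulation serum FSH and oocyte
yield change slope at some breakpoint, and where is it?

The package is aimed at reproductive-medicine biostatisticians analysing
controlled-ovarian-stimulation data, where the exposure is serum FSH on
stimulation Day 7 (mIU/mL), the outcome is the number of oocytes retrieved,
and women contribute repeated IVF cycles (so observations are clustered by
patient). Everything runs equally on any cohort with that shape — a
continuous exposure, a count-like outcome, and a cluster identifier.

## The model

A continuity-constrained two-piece linear mean with breakpoint *K*:

```
FSH <  K :  E[Y] = β₀ + β₁ (FSH − K) + Σᵢ γᵢ Zᵢ
FSH >= K :  E[Y] = β₀ + β₂ (FSH − K) + Σᵢ γᵢ Zᵢ
```

Both segments equal β₀ + Σ γᵢZᵢ at FSH = K, so the fitted mean is
continuous. Coefficients are estimated by generalized estimating equations
(Gaussian, identity link) with an exchangeable working correlation across a
patient's cycles and robust sandwich standard errors. The breakpoint is
found by a recursive quasi-likelihood search (5th–95th exposure percentiles
at 5-percentile steps, then a ±4-percentile refinement at 1-percentile
steps), with:

- a nonparametric **cluster bootstrap** percentile CI for K (patients
  resampled with replacement, full search re-run per replicate);
- a **quasi-likelihood-ratio test** of the segmented versus the simple
  linear model (χ²₁ reference, flagged as anti-conservative because K is
  estimated);
- **10-fold cross-validation** with folds partitioning patients;
- the surrounding screening machinery: tertile descriptives with
  ANOVA/Kruskal–Wallis/χ² group tests, univariate and multivariable-adjusted
  linear screens with a tertile trend test, a penalized-spline (GAM)
  nonlinearity screen, subgroup analyses with interaction tests, and
  first-cycle-only / gonadotropin-type sensitivity reruns.

A synthetic-cohort generator with a known piece-wise-linear truth,
study-like covariate marginals, a Gaussian-copula exposure–covariate
dependence and a patient random intercept drives all validation, so the
entire pipeline is exercisable without any external data. See
`docs/methods.md` for the full methodological account.

## Worked example

```python
from fshthreshold import (default_study_config, simulate_cohort,
    recursive_threshold_search, bootstrap_breakpoint_ci, qlr_threshold_test,
    cross_validate_threshold)

covs = ("age", "amh", "afc", "fsh_day1", "bmi", "pcos", "por")
cfg = default_study_config(n_patients=3000, seed=1, round_and_clip=False)
cohort = simulate_cohort(cfg)          # truth: K=9.13, slopes 1.18 / -0.07

res = recursive_threshold_search(cohort, covs)
lo, hi = bootstrap_breakpoint_ci(cohort, covs, B=200, seed=2)
qlr = qlr_threshold_test(cohort, res.fit, covs)
cv = cross_validate_threshold(cohort, covs, folds=10, seed=3)
```

Output (printed by the snippet above):

```
cycles: 3771  patients: 3000
breakpoint K = 9.18 mIU/mL (bootstrap 95% CI 8.62-10.54)
slope below K = 1.01 (95% CI 0.82, 1.21)
slope above K = -0.07 (95% CI -0.11, -0.03)
QLR threshold test p = 1.3e-24
10-fold CV MSE: segmented 15.79 vs linear 16.22
```

Reading it: on a simulated cohort whose true breakpoint is 9.13 mIU/mL with
segment slopes 1.18 (below) and −0.07 (above), the search recovers the kink
at 9.18; below it each extra mIU/mL of Day-7 FSH predicts about one more
oocyte, above it a slight decrease; the threshold test overwhelmingly
prefers the segmented model, and cross-validated prediction error agrees.

The same analysis runs from the shell on a CSV cohort
(`patient_id, cycle_index, fsh_day7, oocytes, age, amh, ...`; see
`fshthreshold simulate --help` for a generator of the exact schema):

```sh
fshthreshold simulate --n-patients 3000 --seed 1 --out cohort.csv
fshthreshold analyze --input cohort.csv --out run/ --seed 1
fshthreshold report run/
```

`analyze` writes a report bundle — exclusion flow counts, tertile baseline
table, univariate and adjusted screens, the smooth dose–response curve
(CSV + PNG), the threshold analysis, CV summary, subgroup table,
sensitivity reports, and a manifest that makes the run reproducible from
config + seed alone.

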