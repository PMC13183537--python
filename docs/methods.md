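# Methods

`fshthreshold` implements a threshold (two-piece segmented) regression
analysis of a continuous exposure against a count-like outcome in clustered
clinical data. The motivating application is controlled ovarian stimulation:
serum FSH measured on stimulation Day 7 (mIU/mL) as the exposure, number of
oocytes retrieved as the outcome, and the patient as the cluster, since women
may contribute more than one IVF cycle.

## The segmented mean model

For exposure $F$, breakpoint $K$, and covariates $Z_i$:

$$
E[Y] =
\begin{cases}
\beta_0 + \beta_1 (F - K) + \sum_i \gamma_i Z_i, & F < K\\
\beta_0 + \beta_2 (F - K) + \sum_i \gamma_i Z_i, & F \ge K
\end{cases}
$$

Both branches equal $\beta_0 + \sum_i \gamma_i Z_i$ at $F = K$, so the mean
is continuous by construction. The model is fitted on the hinge basis
$\{(F-K)\,[F<K],\ (F-K)\,[F\ge K]\}$, whose columns sum to $F-K$ and both
vanish at $K$.

## Estimation: Gaussian GEE

Because cycles of the same patient are correlated, coefficients are
estimated by generalized estimating equations with identity link, an
exchangeable working correlation (common within-patient correlation
$\alpha$), and robust sandwich standard errors, which remain valid if the
working structure is wrong. The solver alternates a weighted least-squares
step — using the closed-form inverse of the exchangeable working covariance,
$V^{-1} \propto I - \frac{\alpha}{1+(m-1)\alpha} J$ per cluster of size $m$
— with moment updates of the dispersion $\phi$ and of $\alpha$ from
standardized residual cross-products. Convergence tolerance is $10^{-8}$ on
the coefficients with a cap of 100 iterations; $\alpha$ is clamped inside
the positive-definiteness region $(-1/(m_{\max}-1), 1)$. With singleton
clusters (or an independence working structure) the estimating equations
reduce exactly to OLS and the sandwich to the HC0 covariance; the test suite
asserts both identities at $10^{-8}$ and cross-checks the clustered fit
against an independent GEE implementation (statsmodels).

Both $\phi$ and the common $1/(1-\alpha)$ factor cancel algebraically from
the coefficient solve and the sandwich, so one fit costs a handful of dense
matrix products. This matters: a breakpoint search inside a cluster
bootstrap multiplies into roughly $10^5$–$10^6$ refits.

## Breakpoint search

The quasi-likelihood of a candidate breakpoint is the Gaussian log
quasi-likelihood $QL = -\mathrm{RSS} / (2\hat\phi_{\mathrm{lin}})$, with the
dispersion held fixed at the *linear-model* estimate for the dataset so that
comparing candidates is monotone in the residual sum of squares. During the
search the working correlation $\alpha$ is also held fixed at the
linear-model estimate, making each candidate evaluation a single weighted
least-squares solve; the final model at the winning breakpoint is re-fitted
by the full GEE alternation. The search is recursive:

1. evaluate candidates at the 5th–95th exposure percentiles in 5-percentile
   steps;
2. re-scan a ±4-percentile window around the stage-1 winner in 1-percentile
   steps, clamped to [5th, 95th];
3. the breakpoint maximizing the quasi-likelihood over every evaluated
   candidate wins; exact ties break toward the smallest candidate.

Candidates leaving fewer than `min_segment` observations on either side
(default `max(20, 2 × n_parameters)`) are skipped and logged. The recursive
search provably equals exhaustive evaluation over its union candidate set;
the suite verifies this on 50 simulated cohorts against an independent
dense-matrix evaluator.

## Breakpoint confidence interval

Nonparametric cluster bootstrap: patients (not cycles) are resampled with
replacement to the original cluster count, the full two-stage search is
re-run per replicate, and the 2.5th/97.5th percentiles of the replicate
breakpoints form the 95% CI (1000 replicates by default; coverage of the
true breakpoint is verified by simulation at B = 200). Resampling clusters
rather than rows preserves the within-patient correlation.

## Threshold test

The segmented model is compared with the simple linear model via
$2(QL_{\mathrm{seg}} - QL_{\mathrm{lin}})$ referred to $\chi^2_1$ (one extra
slope). At a *fixed* breakpoint this statistic is well calibrated
(simulated type-I error 0.04 at nominal 0.05). When the breakpoint is
estimated by maximizing over the candidate grid, the same reference is
anti-conservative — effectively a sup-statistic over ~27 correlated
candidates; under the null the simulated rejection rate at the 0.05 level is
about 0.22–0.24 under the default study conditions. The returned metadata
says so explicitly; Davies-type corrections are out of scope. Power is not
the issue: at the default kink magnitude (1.18 vs −0.07) and n = 3000
patients, p < 0.001 essentially always.

## Cross-validation

K-fold (default 10) with folds partitioning *patients*, so no patient's
cycles appear in both train and test. Per fold the search and both model
fits run on the training clusters and the mean squared prediction error is
scored on held-out cycles, for the segmented and the linear model.

## Nonlinearity screen

Before threshold modelling, a covariate-adjusted penalized spline screens
for nonlinearity: cubic B-splines with ~10 interior knots at exposure
quantiles, the exact integrated-squared-second-derivative penalty, and GCV
for the smoothing parameter. The penalty null space (constant + linear) is
split out by eigen-reparametrization, so an infinite penalty collapses the
smooth exactly to the linear fit (asserted at 1e-6) and the reported smooth
edf has a floor of 1.

The nonlinearity p-value is an unpenalized nested F test of the
spline-deviation columns against the linear model, which is exact under a
Gaussian null. An edf-based F comparison of the *penalized* fit was
implemented first and rejected: when GCV shrinks the smooth away the
effective df approaches zero and the ratio explodes (simulated null
rejection 0.74); the nested unpenalized comparison measures 0.03 at nominal
0.05. The penalized fit still provides the reported curve, band, and edf.
Curves are evaluated on 200 points spanning the 1st–99th exposure
percentiles, where spline fits are stable.

## Synthetic cohorts

The generator produces the data structure the analysis assumes, with every
parameter explicit and a single seed:

- **Exposure**: a three-component log-normal mixture whose component means
  and SDs match the observed exposure tertiles (8.1 ± 1.5, 13.0 ± 1.4,
  19.2 ± 3.3 mIU/mL). The default breakpoint 9.13 sits near the 26th
  percentile, inside the search grid.
- **Covariates**: marginals at the reported cohort moments (age
  32.7 ± 4.8 y, AMH 3.5 ± 3.8 ng/mL, AFC 8.0 ± 5.0, …), tied to the
  exposure through a one-factor Gaussian copula (each covariate correlates
  with the exposure's latent normal; e.g. AMH at −0.75, age at +0.50).
  Default correlations reproduce the qualitative tertile trends only.
- **Outcome**: the segmented mean (default slopes 1.18 below / −0.07 above
  the breakpoint, covariate effects chosen so the marginal outcome is
  ≈ 9.4 ± 6 oocytes, with the intercept solved in closed form from the
  mixture's partial expectations) plus Gaussian noise decomposed into a
  patient random intercept and cycle error: total SD `sigma` (default 4)
  and intra-patient correlation `icc` (default 0.3). No reference estimate
  exists for either value; both are documented placeholders. Outcomes are
  rounded and clipped at zero by default for schema realism; recovery and
  calibration experiments disable rounding/clipping so the data-generating
  process matches the linear model class being validated.
- **Repeated cycles**: each patient contributes a second cycle with
  probability 0.25; covariates and exposure are redrawn per cycle, and only
  the random intercept is shared.

What the generator does *not* emulate: a true count distribution
(over-dispersion, zero-inflation), informative dose adjustment within
cycles, time trends, or the full joint covariate distribution. Passing
recovery tests therefore show correctness of the estimator chain under its
own assumptions, not robustness to real-data misspecification.

## Conventions and degenerate inputs

- Tertile cuts are type-7 (linear-interpolation) quantiles; values exactly
  at a cut join the lower group (closed lower intervals).
- Complete-case analysis per model, with the rows used recorded
  (`n_used` / `n_obs`).
- Reference level for categorical covariates: most frequent, overridable.
- ANOVA vs Kruskal–Wallis: |skewness| > 1 routes a continuous variable to
  the rank test.
- OLS screening uses t-based intervals; GEE fits use normal quantiles.
- Zero residual variance (noiseless data) short-circuits the α update and
  the quasi-likelihood uses a guarded dispersion, so exact-fit inputs do
  not divide by zero.
- All stochastic operations (simulation, bootstrap, CV folds) take an
  explicit seed; there is no hidden global random state.

## Problem sizes

Simulation-based checks default to the study-scale conditions (3000
patients, ~3750 cycles) with 100-replicate outer loops, 200-replicate
bootstraps, and 1000-replicate null-calibration runs; these sizes give
Monte-Carlo error comfortably below the margins being asserted while a full
suite run stays in the minutes range on one core.

## Known limitations

- One breakpoint only; no Davies-corrected threshold inference; no
  profile-likelihood CI for K.
- The QLR p-value is anti-conservative when K is estimated (see above).
- Gaussian working model for a count outcome, mirroring the analysis design
  it implements; a negative-binomial GEE would be a natural extension.
- The bootstrap treats the breakpoint grid as part of the estimator, so CI
  endpoints inherit the percentile-grid granularity (~0.17 mIU/mL near the
  default breakpoint).
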