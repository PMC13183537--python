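"""Descriptive tertile tables, univariate screening, adjusted models, trend test.

Continuous variables are compared across tertile groups with one-way ANOVA
or, when skewed, the Kruskal-Wallis H test; categorical variables with the
chi-square test on the contingency table.  Linear effects come from ordinary
least squares with classical t-based confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fshthreshold._design import (
    as_frame,
    complete_cases,
    covariate_matrix,
    dummy_columns,
    is_categorical,
)
from fshthreshold.exceptions import (
    CollinearityError,
    ConfigurationError,
    StratumError,
)

#: |skewness| beyond which a continuous variable is treated as skewed and
#: compared with Kruskal-Wallis instead of ANOVA
SKEWNESS_CUTOFF = 1.0

GROUP_ORDER = ("low", "medium", "high")


@dataclass
class GroupComparisonRow:
    """One row of the baseline (tertile) comparison table."""

    variable: str
    summaries: dict  # group -> formatted summary string
    test: str  # anova | kruskal_wallis | chi_square
    statistic: float
    p_value: float
    level: str | None = None  # set for categorical sub-rows


@dataclass
class LinearEffect:
    """A linear regression effect with normal-theory inference."""

    exposure: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    adjusted_for: tuple = ()
    level: str | None = None  # non-reference level for categorical exposures


def _ols(y: np.ndarray, X: np.ndarray, names=None):
    """Least squares with t-based inference; raises on rank deficiency."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [
            names[i] if names else f"column {i}"
            for i in np.flatnonzero(diag <= tol)
        ]
        raise CollinearityError(f"rank-deficient design; aliased: {aliased}", aliased)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    s2 = float(resid @ resid) / max(dof, 1)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p_values = 2 * stats.t.sf(np.abs(t), max(dof, 1))
    tq = stats.t.ppf(0.975, max(dof, 1))
    return beta, se, p_values, (beta - tq * se, beta + tq * se), dof


def baseline_table(cohort, group: str = "tertile", variables=None) -> list:
    """Per-variable group comparison across tertiles (descriptive table).

    Continuous variables: mean +- SD per group, ANOVA or Kruskal-Wallis by
    the skewness policy.  Categorical: n (%) per level, one chi-square test
    on the full contingency table.
    """
    df = as_frame(cohort)
    if group not in df.columns:
        raise ConfigurationError(f"grouping column {group!r} not assigned")
    labels = [g for g in GROUP_ORDER if (df[group] == g).any()] or sorted(
        df[group].dropna().unique()
    )
    if len(labels) < 2:
        raise StratumError("need at least 2 non-empty groups")
    for g in labels:
        if not (df[group] == g).any():
            raise StratumError(f"group {g!r} has zero records")
    if variables is None:
        variables = [
            c
            for c in df.columns
            if c not in ("patient_id", group, "first_cycle") and df[c].notna().any()
        ]
    rows: list[GroupComparisonRow] = []
    for var in variables:
        s = df[var]
        if is_categorical(s):
            levels = sorted(s.dropna().unique())
            table = np.array(
                [[int(((df[group] == g) & (s == lv)).sum()) for g in labels]
                 for lv in levels]
            )
            table = table[table.sum(axis=1) > 0]
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            for lv in levels:
                counts = {
                    g: int(((df[group] == g) & (s == lv)).sum()) for g in labels
                }
                tot = {g: int(((df[group] == g) & s.notna()).sum()) for g in labels}
                rows.append(
                    GroupComparisonRow(
                        variable=var,
                        level=str(lv),
                        summaries={
                            g: f"{counts[g]} ({100 * counts[g] / max(tot[g], 1):.1f}%)"
                            for g in labels
                        },
                        test="chi_square",
                        statistic=float(stat),
                        p_value=float(p),
                    )
                )
        else:
            groups = [
                s[(df[group] == g) & s.notna()].to_numpy(float) for g in labels
            ]
            pooled = s.dropna().to_numpy(float)
            skewed = abs(stats.skew(pooled)) > SKEWNESS_CUTOFF
            if skewed:
                stat, p = stats.kruskal(*groups)
                test = "kruskal_wallis"
            else:
                stat, p = stats.f_oneway(*groups)
                test = "anova"
            rows.append(
                GroupComparisonRow(
                    variable=var,
                    summaries={
                        g: f"{np.mean(v):.2f} ± {np.std(v, ddof=1):.2f}"
                        for g, v in zip(labels, groups)
                    },
                    test=test,
                    statistic=float(stat),
                    p_value=float(p),
                )
            )
    return rows


def univariate_effects(
    cohort,
    outcome: str = "oocytes",
    exposures=(),
    refs: dict | None = None,
    on_singular: str = "warn",
) -> list:
    """Simple (one exposure at a time) linear regressions on the outcome.

    Categorical exposures are expanded against a reference level (most
    frequent unless overridden via ``refs``) and yield one effect row per
    non-reference level.  A constant (singular) exposure is skipped with a
    warning by default (``on_singular="raise"`` aborts instead); other
    exposures are unaffected.
    """
    import warnings

    df = as_frame(cohort)
    refs = refs or {}
    out: list[LinearEffect] = []
    for exp in exposures:
        sub = complete_cases(df, [outcome, exp])
        y = sub[outcome].to_numpy(float)
        s = sub[exp]
        if not is_categorical(s) and np.ptp(s.to_numpy(float)) == 0:
            err = CollinearityError(f"exposure {exp!r} is constant", [exp])
            if on_singular == "raise":
                raise err
            warnings.warn(str(err))
            continue
        if is_categorical(s):
            dummies, _ref = dummy_columns(s, exp, refs.get(exp))
            X = np.column_stack([np.ones(len(sub))] + [v for _, v in dummies])
            names = ["intercept"] + [n for n, _ in dummies]
            beta, se, pv, (lo, hi), _ = _ols(y, X, names)
            for j, (nm, _) in enumerate(dummies, start=1):
                level = nm[nm.index("[") + 1 : -1]
                out.append(
                    LinearEffect(
                        exposure=exp,
                        level=level,
                        beta=float(beta[j]),
                        ci_low=float(lo[j]),
                        ci_high=float(hi[j]),
                        p_value=float(pv[j]),
                        n_used=len(sub),
                    )
                )
        else:
            x = s.to_numpy(float)
            X = np.column_stack([np.ones(len(sub)), x])
            beta, se, pv, (lo, hi), _ = _ols(y, X, ["intercept", exp])
            out.append(
                LinearEffect(
                    exposure=exp,
                    beta=float(beta[1]),
                    ci_low=float(lo[1]),
                    ci_high=float(hi[1]),
                    p_value=float(pv[1]),
                    n_used=len(sub),
                )
            )
    return out


def adjusted_effect(
    cohort,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    covariates=(),
    refs: dict | None = None,
) -> LinearEffect:
    """Multivariable linear model; returns the exposure's partial effect."""
    df = as_frame(cohort)
    sub = complete_cases(df, [outcome, exposure, *covariates])
    Z, znames = covariate_matrix(sub, covariates, refs)
    if len(sub) < Z.shape[1] + 2:
        raise ConfigurationError("fewer complete cases than parameters")
    y = sub[outcome].to_numpy(float)
    x = sub[exposure].to_numpy(float)
    X = np.column_stack([np.ones(len(sub)), x, Z])
    names = ["intercept", exposure, *znames]
    beta, se, pv, (lo, hi), _ = _ols(y, X, names)
    return LinearEffect(
        exposure=exposure,
        beta=float(beta[1]),
        ci_low=float(lo[1]),
        ci_high=float(hi[1]),
        p_value=float(pv[1]),
        n_used=len(sub),
        adjusted_for=tuple(covariates),
    )


def trend_test(
    cohort,
    outcome: str = "oocytes",
    covariates=(),
    group: str = "tertile",
) -> float:
    """P for trend: tertile entered as ordinal score 1/2/3 in the adjusted model."""
    df = as_frame(cohort)
    if group not in df.columns:
        raise ConfigurationError(f"grouping column {group!r} not assigned")
    score = df[group].map({g: i + 1 for i, g in enumerate(GROUP_ORDER)})
    if score.dropna().nunique() < 3:
        raise StratumError("fewer than 3 tertile groups represented")
    work = df.assign(_tertile_score=score.astype(float))
    eff = adjusted_effect(work, "_tertile_score", outcome, covariates)
    return eff.p_value


def effects_table(effects: list) -> pd.DataFrame:
    """Flatten LinearEffect rows to a DataFrame (CSV-friendly)."""
    return pd.DataFrame(
        [
            {
                "exposure": e.exposure,
                "level": e.level,
                "beta": e.beta,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "n_used": e.n_used,
                "adjusted_for": ";".join(e.adjusted_for),
            }
            for e in effects
        ]
    )


def baseline_frame(rows: list) -> pd.DataFrame:
    """Flatten GroupComparisonRow rows to a DataFrame."""
    recs = []
    for r in rows:
        rec = {"variable": r.variable, "level": r.level, "test": r.test,
               "statistic": r.statistic, "p_value": r.p_value}
        rec.update(r.summaries)
        recs.append(rec)
    return pd.DataFrame(recs)
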