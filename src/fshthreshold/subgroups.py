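"""Stratified exposure effects with interaction tests, and sensitivity reruns.

Strata follow the study's clinical axes (age 35 years; AMH 1.2 and 5 ng/mL;
BMI 18.5 kg/m2; POR; PCOS).  Within each stratum the adjusted linear
exposure effect is reported with the stratifying variable removed from the
adjustment set; the interaction p-value is a joint Wald F test on the
exposure-by-stratum product terms in the pooled adjusted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fshthreshold._design import as_frame, complete_cases, covariate_matrix
from fshthreshold.cohort import GONADOTROPIN_TYPES, first_cycle_subset, Cohort
from fshthreshold.exceptions import (
    ConfigurationError,
    FshThresholdError,
    StratumError,
)
from fshthreshold.gam import fit_smooth
from fshthreshold.screening import LinearEffect, adjusted_effect
from fshthreshold.threshold import (
    GEESpec,
    SearchConfig,
    bootstrap_breakpoint_ci,
    qlr_threshold_test,
    recursive_threshold_search,
)


@dataclass
class StratumDef:
    """One stratifying axis: numeric cut points, or levels of a discrete field."""

    variable: str
    cuts: tuple | None = None  # ascending numeric cuts; None = discrete levels


#: study-default subgroup axes
DEFAULT_STRATA = (
    StratumDef("age", (35,)),
    StratumDef("amh", (1.2, 5)),
    StratumDef("bmi", (18.5,)),
    StratumDef("por", None),
    StratumDef("pcos", None),
)


@dataclass
class SubgroupResult:
    """Per-stratum exposure effects plus the pooled interaction test."""

    variable: str
    labels: list
    n_per_stratum: dict
    effects: dict  # label -> LinearEffect (skipped strata absent)
    p_interaction: float
    skipped: list = field(default_factory=list)


def _stratum_labels(values: np.ndarray, d: StratumDef):
    """Exhaustive, mutually exclusive labels (cuts: closed on the right
    boundary of the lower interval mirrors the tertile convention)."""
    if d.cuts is None:
        uniq = sorted(np.unique(values[~_isnan(values)]))
        labels = np.array([None] * len(values), dtype=object)
        for lv in uniq:
            labels[values == lv] = str(lv)
        return labels, [str(lv) for lv in uniq]
    cuts = sorted(d.cuts)
    edges = [-np.inf, *cuts, np.inf]
    names = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == -np.inf:
            names.append(f"<{hi:g}")
        elif hi == np.inf:
            names.append(f">={lo:g}")
        else:
            names.append(f"{lo:g}-{hi:g}")
    v = np.asarray(values, float)
    idx = np.searchsorted(cuts, v, side="right")
    labels = np.array([None] * len(v), dtype=object)
    ok = np.isfinite(v)
    labels[ok] = np.asarray(names, dtype=object)[idx[ok]]
    return labels, names


def _isnan(values):
    try:
        return np.isnan(np.asarray(values, float))
    except (TypeError, ValueError):
        return np.zeros(len(values), bool)


def _interaction_pvalue(df, exposure, outcome, labels, covariates):
    """Joint Wald F test across exposure-by-stratum product terms (pooled OLS)."""
    y = df[outcome].to_numpy(float)
    x = df[exposure].to_numpy(float)
    Z, _ = covariate_matrix(df, covariates)
    lev = [l for l in dict.fromkeys(labels) if l is not None]
    ref, others = lev[0], lev[1:]
    dums = np.column_stack([(labels == l).astype(float) for l in others]) if others else np.empty((len(y), 0))
    prods = dums * x[:, None]
    X = np.column_stack([np.ones(len(y)), x, dums, prods, Z])
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    k = prods.shape[1]
    if k == 0:
        raise StratumError("need at least 2 strata for an interaction test")
    sl = slice(2 + len(others), 2 + len(others) + k)
    br = beta[sl]
    Vr = cov[sl, sl]
    fstat = float(br @ np.linalg.solve(Vr, br)) / k
    return float(stats.f.sf(fstat, k, dof))


def stratified_effects(
    cohort,
    strata=DEFAULT_STRATA,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    covariates=(),
    min_n: int = 30,
) -> list:
    """Adjusted exposure effect within each stratum of each axis, plus the
    interaction p-value; the stratifying variable is dropped from adjustment."""
    df = as_frame(cohort)
    out = []
    for d in strata:
        if d.variable not in df.columns:
            raise StratumError(f"stratifying variable {d.variable!r} absent")
        adj = [c for c in covariates if c != d.variable]
        sub = complete_cases(df, [outcome, exposure, d.variable, *adj])
        labels, names = _stratum_labels(sub[d.variable].to_numpy(), d)
        n_per = {nm: int(np.sum(labels == nm)) for nm in names}
        effects: dict = {}
        skipped = []
        for nm in names:
            mask = labels == nm
            if n_per[nm] < min_n:
                warnings.warn(
                    f"stratum {d.variable}={nm}: n={n_per[nm]} < {min_n}; skipped"
                )
                skipped.append(nm)
                continue
            effects[nm] = adjusted_effect(
                sub[mask], exposure, outcome, covariates=adj
            )
        present = [nm for nm in names if n_per[nm] > 0]
        if len(present) >= 2:
            keep = np.isin(labels, present)
            p_int = _interaction_pvalue(
                sub[keep], exposure, outcome, labels[keep], adj
            )
        else:
            p_int = float("nan")
        out.append(
            SubgroupResult(
                variable=d.variable,
                labels=names,
                n_per_stratum=n_per,
                effects=effects,
                p_interaction=p_int,
                skipped=skipped,
            )
        )
    return out


# ---------------------------------------------------------------------------
# sensitivity designs (full threshold pipeline on a subset)


def threshold_report(
    cohort,
    covariates=(),
    spec: GEESpec | None = None,
    config: SearchConfig | None = None,
    bootstrap_B: int = 1000,
    seed: int = 0,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    run_gam: bool = True,
) -> dict:
    """Nonlinearity screen + threshold search + bootstrap CI + QLR test.

    Returns a JSON-ready report; failures yield ``{"status": "failed", ...}``
    rather than raising, so sensitivity subsets degrade gracefully.
    """
    spec = spec or GEESpec()
    df = as_frame(cohort)
    report: dict = {"status": "ok", "n_cycles": int(len(df)),
                    "n_patients": int(df[spec.cluster_field].nunique())}
    stage = "gam"
    try:
        if run_gam:
            sm = fit_smooth(df, exposure, outcome, covariates)
            report["gam"] = {
                "edf": sm.edf,
                "p_nonlinearity": sm.p_nonlinearity,
            }
        stage = "search"
        res = recursive_threshold_search(
            df, covariates, spec, config, exposure=exposure, outcome=outcome
        )
        report["K"] = res.K_opt
        report["fit"] = res.fit.to_dict()
        report["profile"] = [
            {"stage": s, "percentile": r["percentile"], "K": r["K"],
             "ql": r["ql"], "skipped": r["skipped"]}
            for s, rows in ((1, res.stage1), (2, res.stage2))
            for r in rows
        ]
        stage = "qlr"
        report["qlr"] = qlr_threshold_test(
            df, res.fit, covariates, spec, exposure=exposure, outcome=outcome
        )
        if bootstrap_B:
            stage = "bootstrap"
            lo, hi = bootstrap_breakpoint_ci(
                df, covariates, spec, config, B=bootstrap_B, seed=seed,
                exposure=exposure, outcome=outcome,
            )
            report["bootstrap_ci"] = [lo, hi]
            report["bootstrap_B"] = bootstrap_B
        else:
            report["bootstrap_ci"] = None
    except FshThresholdError as exc:
        report.update(
            {"status": "failed", "stage": stage, "error": str(exc),
             "error_type": type(exc).__name__}
        )
    return report


def sensitivity_first_cycle(
    cohort,
    covariates=(),
    spec: GEESpec | None = None,
    config: SearchConfig | None = None,
    bootstrap_B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Rerun the threshold pipeline on one cycle per patient (clusters become
    singletons, so the GEE reduces to robust-variance least squares)."""
    try:
        sub = first_cycle_subset(
            cohort if isinstance(cohort, Cohort) else Cohort(as_frame(cohort))
        )
    except FshThresholdError as exc:
        return {"status": "failed", "stage": "first_cycle_subset",
                "error": str(exc), "error_type": type(exc).__name__}
    report = threshold_report(
        sub, covariates, spec, config, bootstrap_B, seed, **kwargs
    )
    report["design"] = "first_cycle_only"
    return report


def sensitivity_gonadotropin_subset(
    cohort,
    gonadotropin_type: str,
    covariates=(),
    spec: GEESpec | None = None,
    config: SearchConfig | None = None,
    bootstrap_B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Rerun the threshold pipeline restricted to one gonadotropin type."""
    if gonadotropin_type not in GONADOTROPIN_TYPES:
        raise ConfigurationError(
            f"unknown gonadotropin type {gonadotropin_type!r}; "
            f"valid: {GONADOTROPIN_TYPES}"
        )
    df = as_frame(cohort)
    sub = df[df["gonadotropin_type"] == gonadotropin_type]
    if len(sub) == 0:
        return {"status": "failed", "stage": "subset",
                "error": f"no cycles with gonadotropin_type={gonadotropin_type!r}",
                "error_type": "EmptyInputError"}
    report = threshold_report(
        sub, covariates, spec, config, bootstrap_B, seed, **kwargs
    )
    report["design"] = f"gonadotropin_{gonadotropin_type}"
    return report
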