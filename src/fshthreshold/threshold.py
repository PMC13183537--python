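"""Two-piece continuity-constrained segmented regression with GEE.

Mean structure (continuous at the breakpoint K by construction):

    FSH <  K:  E[Y] = beta0 + beta1 * (FSH - K) + sum_i gamma_i Z_i
    FSH >= K:  E[Y] = beta0 + beta2 * (FSH - K) + sum_i gamma_i Z_i

The breakpoint is found by a two-stage recursive search that maximizes the
Gaussian quasi-likelihood over exposure-percentile candidates (global 5th to
95th percentile scan at 5-percentile steps, then a +-4-percentile window at
1-percentile steps), with a cluster bootstrap percentile CI, a
quasi-likelihood-ratio test against the simple linear model, and
cluster-aware k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from fshthreshold._design import as_frame, complete_cases, covariate_matrix
from fshthreshold.exceptions import (
    BootstrapError,
    ComparisonError,
    ConfigurationError,
    FoldError,
    SearchError,
)
from fshthreshold.gee import cluster_blocks, fit_gee, solve_beta


@dataclass
class GEESpec:
    """Estimation specification: clustering and working correlation."""

    cluster_field: str = "patient_id"
    working_correlation: str = "exchangeable"  # or "independence"
    covariance: str = "robust"  # sandwich; the only supported type

    def __post_init__(self):
        if self.working_correlation not in ("exchangeable", "independence"):
            raise ConfigurationError(
                f"unknown working correlation {self.working_correlation!r}"
            )


@dataclass
class SearchConfig:
    """Percentile grid for the recursive breakpoint search."""

    grid_start: float = 5.0
    grid_stop: float = 95.0
    grid_step: float = 5.0
    refine_halfwidth: float = 4.0
    refine_step: float = 1.0
    min_segment: int | None = None  # default: max(20, 2 * n_params)


@dataclass
class SegmentedFit:
    """Fitted two-piece GEE model at a given breakpoint."""

    K: float
    beta0: float
    beta1: float
    beta2: float
    gamma: dict
    se: dict
    ci: dict
    quasi_likelihood: float
    phi_ref: float
    rss: float
    alpha: float
    phi: float
    n_obs: int
    n_clusters: int
    converged: bool
    names: list
    params: np.ndarray
    cov: np.ndarray
    spec: GEESpec

    def predict(self, fsh, Z: np.ndarray | None = None):
        """Marginal mean at exposure values (and optional covariate matrix)."""
        fsh = np.asarray(fsh, float)
        d = fsh - self.K
        out = self.beta0 + np.where(d < 0, self.beta1 * d, self.beta2 * d)
        if Z is not None:
            g = self.params[3:]
            out = out + np.asarray(Z, float) @ g
        return out

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "gamma": self.gamma,
            "se": self.se,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "quasi_likelihood": self.quasi_likelihood,
            "alpha": self.alpha,
            "phi": self.phi,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "working_correlation": self.spec.working_correlation,
        }


@dataclass
class ThresholdSearchResult:
    """Trace and outcome of the recursive quasi-likelihood search."""

    stage1: list
    stage2: list
    K_opt: float
    fit: SegmentedFit
    phi_ref: float
    alpha_used: float
    rss_linear: float
    config: SearchConfig
    bootstrap_ci: tuple | None = None
    qlr: dict | None = None
    cv: dict | None = None

    @property
    def trace(self) -> list:
        return self.stage1 + self.stage2

    def to_dict(self) -> dict:
        return {
            "K_opt": self.K_opt,
            "fit": self.fit.to_dict(),
            "bootstrap_ci": list(self.bootstrap_ci) if self.bootstrap_ci else None,
            "qlr": self.qlr,
            "cv": self.cv,
            "stage1": self.stage1,
            "stage2": self.stage2,
        }


# ---------------------------------------------------------------------------
# basis and data preparation


def hinge_design(fsh, K: float):
    """Continuity-constrained basis: ``((fsh-K)*[fsh<K], (fsh-K)*[fsh>=K])``.

    The columns sum to ``fsh - K`` everywhere and both vanish at ``fsh = K``,
    which is what makes the fitted mean continuous at the breakpoint.
    """
    if not np.isfinite(K):
        raise ConfigurationError("breakpoint K must be finite")
    fsh = np.asarray(fsh, float)
    d = fsh - K
    below = np.where(d < 0, d, 0.0)
    above = np.where(d >= 0, d, 0.0)
    return below, above


def _prepare(cohort, exposure, outcome, covariates, spec):
    """Complete-case arrays sorted by cluster."""
    df = as_frame(cohort)
    cols = [spec.cluster_field, exposure, outcome, *covariates]
    sub = complete_cases(df, cols)
    if len(sub) == 0:
        raise SearchError("no complete-case records to fit")
    Z, znames = covariate_matrix(sub, covariates)
    ids = sub[spec.cluster_field].to_numpy()
    order, starts, sizes = cluster_blocks(ids)
    y = sub[outcome].to_numpy(float)[order]
    fsh = sub[exposure].to_numpy(float)[order]
    Z = Z[order]
    return {
        "y": y,
        "fsh": fsh,
        "Z": Z,
        "znames": znames,
        "starts": starts,
        "sizes": sizes,
        "ids": ids[order],
        "frame": sub.iloc[order],
    }


def _design_segmented(fsh, K, Z):
    below, above = hinge_design(fsh, K)
    return np.column_stack([np.ones(len(fsh)), below, above, Z])


def _design_linear(fsh, Z):
    return np.column_stack([np.ones(len(fsh)), fsh, Z])


# ---------------------------------------------------------------------------
# fitting


def fit_segmented_gee(
    cohort,
    K: float,
    covariates=(),
    spec: GEESpec | None = None,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    phi_ref: float | None = None,
) -> SegmentedFit:
    """Fit the two-piece model at a fixed breakpoint K.

    ``phi_ref`` is the dispersion used in the reported quasi-likelihood; by
    default it is estimated from the simple linear GEE model on the same
    rows, so quasi-likelihoods of different candidate breakpoints are
    comparable.
    """
    spec = spec or GEESpec()
    d = _prepare(cohort, exposure, outcome, covariates, spec)
    y, fsh, Z = d["y"], d["fsh"], d["Z"]
    if not (np.nanmin(fsh) < K < np.nanmax(fsh)):
        raise ConfigurationError(
            f"K={K} is not strictly inside the observed exposure range"
        )
    names = ["beta0", "beta1", "beta2", *d["znames"]]
    X = _design_segmented(fsh, K, Z)
    res = fit_gee(
        y, X, d["starts"], d["sizes"], spec.working_correlation, names=names
    )
    if phi_ref is None:
        lin = fit_gee(
            y,
            _design_linear(fsh, Z),
            d["starts"],
            d["sizes"],
            spec.working_correlation,
            check_rank=False,
        )
        phi_ref = lin.phi
    z = norm.ppf(0.975)
    ci = {nm: (b - z * s, b + z * s) for nm, b, s in zip(names, res.beta, res.se)}
    return SegmentedFit(
        K=float(K),
        beta0=float(res.beta[0]),
        beta1=float(res.beta[1]),
        beta2=float(res.beta[2]),
        gamma=dict(zip(d["znames"], map(float, res.beta[3:]))),
        se=dict(zip(names, map(float, res.se))),
        ci=ci,
        quasi_likelihood=res.quasi_likelihood(phi_ref),
        phi_ref=float(phi_ref),
        rss=res.rss,
        alpha=res.alpha,
        phi=res.phi,
        n_obs=res.n_obs,
        n_clusters=res.n_clusters,
        converged=res.converged,
        names=names,
        params=res.beta,
        cov=res.cov,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# recursive search (array-level core shared by bootstrap and CV)


def _profile_candidates(
    y, fsh, Z, starts, sizes, alpha, phi_ref, cand, min_segment, cache
):
    """Quasi-likelihood of the segmented model at each candidate breakpoint.

    The working correlation and dispersion are held fixed at the linear-model
    estimates for the dataset, so each candidate is one weighted
    least-squares solve and the comparison is monotone in RSS.
    """
    n = len(y)
    X = np.empty((n, 3 + Z.shape[1]))
    X[:, 0] = 1.0
    X[:, 3:] = Z
    rows = []
    for pct, K in cand:
        K = float(K)
        if K in cache:
            rows.append({"percentile": pct, "K": K, "ql": cache[K], "skipped": False})
            continue
        n_below = int(np.sum(fsh < K))
        if n_below < min_segment or n - n_below < min_segment:
            rows.append({"percentile": pct, "K": K, "ql": None, "skipped": True})
            continue
        d = fsh - K
        X[:, 1] = np.where(d < 0, d, 0.0)
        X[:, 2] = np.where(d >= 0, d, 0.0)
        try:
            beta = solve_beta(X, y, starts, sizes, alpha)
        except np.linalg.LinAlgError:
            rows.append({"percentile": pct, "K": K, "ql": None, "skipped": True})
            continue
        e = y - X @ beta
        ql = -float(e @ e) / (2.0 * max(phi_ref, 1e-300))
        cache[K] = ql
        rows.append({"percentile": pct, "K": K, "ql": ql, "skipped": False})
    return rows


def _search_core(y, fsh, Z, starts, sizes, spec, config, min_segment):
    """Two-stage percentile search; returns (K_opt, stage1, stage2, alpha, phi,
    rss_linear).  Raises SearchError when every candidate is inadmissible."""
    lin = fit_gee(
        y,
        _design_linear(fsh, Z),
        starts,
        sizes,
        spec.working_correlation,
        check_rank=False,
    )
    alpha, phi_ref = lin.alpha, lin.phi
    cache: dict = {}

    pcts1 = np.arange(config.grid_start, config.grid_stop + 1e-9, config.grid_step)
    cand1 = list(zip(pcts1, np.percentile(fsh, pcts1)))
    stage1 = _profile_candidates(
        y, fsh, Z, starts, sizes, alpha, phi_ref, cand1, min_segment, cache
    )
    ok1 = [r for r in stage1 if not r["skipped"]]
    if not ok1:
        raise SearchError("all stage-1 candidates violated the minimum segment size")
    best1 = max(ok1, key=lambda r: (r["ql"], -r["K"]))

    lo = max(config.grid_start, best1["percentile"] - config.refine_halfwidth)
    hi = min(config.grid_stop, best1["percentile"] + config.refine_halfwidth)
    pcts2 = np.arange(lo, hi + 1e-9, config.refine_step)
    cand2 = list(zip(pcts2, np.percentile(fsh, pcts2)))
    stage2 = _profile_candidates(
        y, fsh, Z, starts, sizes, alpha, phi_ref, cand2, min_segment, cache
    )

    evaluated = [r for r in stage1 + stage2 if not r["skipped"]]
    # maximal quasi-likelihood; ties broken toward the smallest K
    best = max(evaluated, key=lambda r: (r["ql"], -r["K"]))
    return float(best["K"]), stage1, stage2, alpha, phi_ref, lin.rss


def recursive_threshold_search(
    cohort,
    covariates=(),
    spec: GEESpec | None = None,
    config: SearchConfig | None = None,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
) -> ThresholdSearchResult:
    """Recursive quasi-likelihood maximization over exposure percentiles.

    Stage 1 scans the 5th-95th exposure percentiles at 5-percentile steps;
    stage 2 re-scans a +-4-percentile window around the stage-1 winner at
    1-percentile steps (clamped to the stage-1 bounds).  The final model is
    re-fitted by full GEE at the winning breakpoint.
    """
    spec = spec or GEESpec()
    config = config or SearchConfig()
    d = _prepare(cohort, exposure, outcome, covariates, spec)
    n_params = 3 + d["Z"].shape[1]
    min_segment = (
        config.min_segment
        if config.min_segment is not None
        else max(20, 2 * n_params)
    )
    K_opt, stage1, stage2, alpha, phi_ref, rss_lin = _search_core(
        d["y"], d["fsh"], d["Z"], d["starts"], d["sizes"], spec, config, min_segment
    )
    fit = fit_segmented_gee(
        d["frame"],
        K_opt,
        covariates,
        spec,
        exposure=exposure,
        outcome=outcome,
        phi_ref=phi_ref,
    )
    return ThresholdSearchResult(
        stage1=stage1,
        stage2=stage2,
        K_opt=K_opt,
        fit=fit,
        phi_ref=phi_ref,
        alpha_used=alpha,
        rss_linear=rss_lin,
        config=config,
    )


# ---------------------------------------------------------------------------
# bootstrap CI


def _resample_rows(rng, starts, sizes):
    """Row indices for one cluster bootstrap replicate plus new block bounds."""
    n_clusters = len(starts)
    chosen = rng.integers(0, n_clusters, n_clusters)
    s, m = starts[chosen], sizes[chosen]
    total = int(m.sum())
    offsets = np.zeros(n_clusters, dtype=np.int64)
    np.cumsum(m[:-1], out=offsets[1:])
    rows = np.repeat(s - offsets, m) + np.arange(total)
    new_starts = offsets
    return rows, new_starts, m


def bootstrap_breakpoint_ci(
    cohort,
    covariates=(),
    spec: GEESpec | None = None,
    config: SearchConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    return_replicates: bool = False,
):
    """Cluster (patient-level) nonparametric bootstrap percentile CI for K.

    Resamples patients with replacement to the original cluster count,
    reruns the full recursive search per replicate, and returns the 2.5th
    and 97.5th percentiles of the replicate breakpoints.
    """
    spec = spec or GEESpec()
    config = config or SearchConfig()
    d = _prepare(cohort, exposure, outcome, covariates, spec)
    y, fsh, Z, starts, sizes = d["y"], d["fsh"], d["Z"], d["starts"], d["sizes"]
    min_segment = (
        config.min_segment
        if config.min_segment is not None
        else max(20, 2 * (3 + Z.shape[1]))
    )
    rng = np.random.default_rng(seed)
    ks = np.empty(B)
    failures = []
    n_ok = 0
    for b in range(B):
        rows, st, sz = _resample_rows(rng, starts, sizes)
        try:
            k, *_ = _search_core(
                y[rows], fsh[rows], Z[rows], st, sz, spec, config, min_segment
            )
            ks[n_ok] = k
            n_ok += 1
        except (SearchError, np.linalg.LinAlgError) as exc:
            failures.append({"replicate": b, "error": str(exc)})
    if len(failures) > 0.2 * B:
        raise BootstrapError(
            f"{len(failures)} of {B} bootstrap replicates failed", failures
        )
    lo, hi = np.percentile(ks[:n_ok], [2.5, 97.5])
    if return_replicates:
        return (float(lo), float(hi)), ks[:n_ok].copy()
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# threshold test


def qlr_threshold_test(
    cohort,
    fit: SegmentedFit,
    covariates=(),
    spec: GEESpec | None = None,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
) -> dict:
    """Quasi-likelihood-ratio test: segmented versus simple linear model.

    Statistic ``2 (QL_seg - QL_lin)`` with both quasi-likelihoods evaluated
    at the fixed reference dispersion, referred to chi-square with 1 df (the
    extra slope).  Because the breakpoint is estimated from the same data the
    reference is anti-conservative; the returned metadata says so.
    """
    spec = spec or fit.spec
    d = _prepare(cohort, exposure, outcome, covariates, spec)
    if len(d["y"]) != fit.n_obs:
        raise ComparisonError(
            f"segmented fit used {fit.n_obs} rows but the linear comparison "
            f"has {len(d['y'])}; models must share complete-case rows"
        )
    lin = fit_gee(
        d["y"],
        _design_linear(d["fsh"], d["Z"]),
        d["starts"],
        d["sizes"],
        spec.working_correlation,
        check_rank=False,
    )
    stat = max(0.0, (lin.rss - fit.rss) / max(fit.phi_ref, 1e-300))
    return {
        "statistic": float(stat),
        "df": 1,
        "p_value": float(chi2.sf(stat, 1)),
        "note": (
            "chi-square(1) reference is approximate and anti-conservative "
            "because the breakpoint is estimated from the data"
        ),
    }


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate_threshold(
    cohort,
    covariates=(),
    spec: GEESpec | None = None,
    config: SearchConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
) -> dict:
    """K-fold cross-validation with folds partitioning patients, not cycles.

    Per fold: run the recursive search and fit both models on the training
    clusters, then score mean squared prediction error on held-out cycles.
    """
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    spec = spec or GEESpec()
    config = config or SearchConfig()
    d = _prepare(cohort, exposure, outcome, covariates, spec)
    y, fsh, Z, starts, sizes = d["y"], d["fsh"], d["Z"], d["starts"], d["sizes"]
    n_clusters = len(starts)
    if folds > n_clusters:
        raise FoldError(f"{folds} folds but only {n_clusters} clusters")
    min_segment = (
        config.min_segment
        if config.min_segment is not None
        else max(20, 2 * (3 + Z.shape[1]))
    )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_clusters)
    assignment = np.empty(n_clusters, int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = f
    row_fold = np.repeat(assignment, sizes)

    per_fold = []
    sse = {"segmented": 0.0, "linear": 0.0}
    n_test_total = 0
    for f in range(folds):
        test = row_fold == f
        train = ~test
        if not test.any():
            raise FoldError(f"fold {f} has no test cycles")
        tr_sizes = sizes[assignment != f]
        tr_starts = np.zeros(len(tr_sizes), dtype=np.int64)
        np.cumsum(tr_sizes[:-1], out=tr_starts[1:])
        ytr, ftr, Ztr = y[train], fsh[train], Z[train]
        k, _s1, _s2, _alpha, _phi, _rss = _search_core(
            ytr, ftr, Ztr, tr_starts, tr_sizes, spec, config, min_segment
        )
        seg = fit_gee(
            ytr,
            _design_segmented(ftr, k, Ztr),
            tr_starts,
            tr_sizes,
            spec.working_correlation,
            check_rank=False,
        )
        lin = fit_gee(
            ytr,
            _design_linear(ftr, Ztr),
            tr_starts,
            tr_sizes,
            spec.working_correlation,
            check_rank=False,
        )
        yte, fte, Zte = y[test], fsh[test], Z[test]
        pred_seg = _design_segmented(fte, k, Zte) @ seg.beta
        pred_lin = _design_linear(fte, Zte) @ lin.beta
        mse_seg = float(np.mean((yte - pred_seg) ** 2))
        mse_lin = float(np.mean((yte - pred_lin) ** 2))
        per_fold.append(
            {
                "fold": f,
                "K": float(k),
                "n_test": int(test.sum()),
                "mse_segmented": mse_seg,
                "mse_linear": mse_lin,
            }
        )
        sse["segmented"] += mse_seg * test.sum()
        sse["linear"] += mse_lin * test.sum()
        n_test_total += int(test.sum())
    return {
        "folds": folds,
        "seed": seed,
        "per_fold": per_fold,
        "pooled_mse_segmented": sse["segmented"] / n_test_total,
        "pooled_mse_linear": sse["linear"] / n_test_total,
        "K_per_fold": [r["K"] for r in per_fold],
    }
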