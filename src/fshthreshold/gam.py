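"""Nonlinearity screening with a covariate-adjusted penalized spline.

The dose-response screen fits ``y ~ Z + s(exposure)`` where ``s`` is a cubic
B-spline with knots at exposure quantiles and an exact integrated
squared-second-derivative penalty.  The penalty null space (constant +
linear) is split out explicitly, so driving the penalty to infinity
collapses the model to the plain linear adjustment; the smoothing parameter
is chosen by generalized cross-validation (GCV).  The nonlinearity p-value
is an F-type comparison of the spline fit against the nested linear fit with
effective-degrees-of-freedom based numerator df — approximate, as all such
tests with data-chosen smoothing are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from fshthreshold._design import as_frame, complete_cases, covariate_matrix
from fshthreshold.exceptions import BasisError, ConfigurationError

MIN_COMPLETE_CASES = 50
MIN_DISTINCT_EXPOSURE = 10


@dataclass
class SmoothFit:
    """Penalized-spline dose-response fit on an evaluation grid."""

    grid: np.ndarray
    fit: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    edf: float  # 1 (linear) + nonlinear edf of the smooth
    edf_nonlinear: float
    p_nonlinearity: float
    lambda_: float
    covariates: tuple
    n_obs: int
    rss: float
    rss_linear: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "fit": self.fit,
                "ci_low": self.band_low,
                "ci_high": self.band_high,
            }
        )


def _spline_basis(x: np.ndarray, n_knots: int):
    """Cubic B-spline basis with interior knots at quantiles, plus the exact
    integrated second-derivative penalty matrix."""
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs))
    lo, hi = float(np.min(x)), float(np.max(x))
    interior = interior[(interior > lo) & (interior < hi)]
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    nb = len(t) - 4
    if np.unique(x).size < nb:
        raise BasisError(
            f"{np.unique(x).size} distinct exposure values < basis size {nb}"
        )
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, 3).toarray()

    # exact penalty: B'' is piecewise linear, so per-interval Simpson is exact
    spans = np.unique(t)
    d2 = []
    pts = []
    for a, b in zip(spans[:-1], spans[1:]):
        pts.extend([a, (a + b) / 2, b])
    pts = np.asarray(pts)
    for j in range(nb):
        c = np.zeros(nb)
        c[j] = 1.0
        d2.append(BSpline(t, c, 3, extrapolate=False).derivative(2)(pts))
    D2 = np.nan_to_num(np.column_stack(d2))
    S = np.zeros((nb, nb))
    for i, (a, b) in enumerate(zip(spans[:-1], spans[1:])):
        h = b - a
        fa, fm, fb = D2[3 * i], D2[3 * i + 1], D2[3 * i + 2]
        S += (h / 6) * (np.outer(fa, fa) + 4 * np.outer(fm, fm) + np.outer(fb, fb))
    return t, B, S


def _reparametrize(S: np.ndarray):
    """Rotate the basis so the penalty is the identity on the penalized block
    and the 2-dimensional null space (constant + linear) drops out."""
    w, U = np.linalg.eigh(S)
    tol = max(w.max(), 1.0) * 1e-10
    rng = w > tol
    T = U[:, rng] / np.sqrt(w[rng])
    return T  # maps basis coords -> penalized coords: X_s = B @ T


def fit_smooth(
    cohort,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    covariates=(),
    n_knots: int = 10,
    lambdas=None,
    grid: np.ndarray | None = None,
    grid_size: int = 200,
) -> SmoothFit:
    """Penalized-spline partial effect of the exposure with linear covariate
    adjustment; smoothing parameter by GCV; nonlinearity p-value from the
    spline-versus-linear F comparison."""
    df = as_frame(cohort)
    sub = complete_cases(df, [outcome, exposure, *covariates])
    n = len(sub)
    if n < MIN_COMPLETE_CASES:
        raise ConfigurationError(
            f"{n} complete cases < required {MIN_COMPLETE_CASES}"
        )
    x = sub[exposure].to_numpy(float)
    if np.unique(x).size < MIN_DISTINCT_EXPOSURE:
        raise BasisError(
            f"exposure has {np.unique(x).size} distinct values "
            f"(< {MIN_DISTINCT_EXPOSURE})"
        )
    y = sub[outcome].to_numpy(float)
    Z, _names = covariate_matrix(sub, covariates)

    t, B, S = _spline_basis(x, n_knots)
    T = _reparametrize(S)
    Xs = B @ T
    q = Z.shape[1]
    X = np.column_stack([np.ones(n), Z, x, Xs])
    p_lin = 2 + q  # intercept + covariates + linear exposure
    p_tot = X.shape[1]
    smooth_ix = np.arange(p_lin, p_tot)

    G = X.T @ X
    g = X.T @ y
    yty = float(y @ y)
    D = np.zeros((p_tot, p_tot))
    D[smooth_ix, smooth_ix] = 1.0

    if lambdas is None:
        lambdas = np.logspace(-4, 9, 53) * n
    best = None
    for lam in np.atleast_1d(lambdas):
        M = G + lam * D
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        H = Minv @ G
        edf_tot = float(np.trace(H))
        b = Minv @ g
        rss = max(yty - 2 * b @ g + b @ G @ b, 0.0)
        denom = max(n - edf_tot, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, b, Minv, H, edf_tot, rss)
    if best is None:
        raise ConfigurationError("penalized solve failed for every lambda")
    _, lam, b, Minv, H, edf_tot, rss = best

    edf_nonlin = float(np.sum(np.diag(H)[smooth_ix]))
    # nonlinearity test: unpenalized nested F comparison of the linear model
    # against linear + spline-deviation columns (exact under a Gaussian null;
    # an edf-based comparison of the penalized fit is badly anti-conservative
    # when GCV shrinks the smooth away, so it is not used for the p-value)
    Xl = X[:, :p_lin]
    bl, _, _, _ = np.linalg.lstsq(Xl, y, rcond=None)
    rss_lin = float(np.sum((y - Xl @ bl) ** 2))
    bu, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_unpen = float(np.sum((y - X @ bu) ** 2))
    k_dev = len(smooth_ix)
    df2 = n - p_tot
    if rss_lin <= 1e-10 * yty:
        # the linear model already fits to numerical precision
        p_nl = 1.0
    elif rss_unpen > 0 and df2 > 0:
        fstat = ((rss_lin - rss_unpen) / k_dev) / (rss_unpen / df2)
        p_nl = float(stats.f.sf(max(fstat, 0.0), k_dev, df2))
    else:
        p_nl = 1.0

    s2 = rss / max(n - edf_tot, 1.0)
    cov = s2 * (Minv @ G @ Minv)

    if grid is None:
        glo, ghi = np.percentile(x, [1, 99])
        grid = np.linspace(glo, ghi, grid_size)
    grid = np.asarray(grid, float)
    Bg = BSpline.design_matrix(np.clip(grid, t[0], t[-1]), t, 3).toarray()
    zbar = Z.mean(axis=0) if q else np.empty(0)
    Xg = np.column_stack(
        [np.ones(len(grid)), np.tile(zbar, (len(grid), 1)), grid, Bg @ T]
    )
    curve = Xg @ b
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
    zq = stats.norm.ppf(0.975)
    return SmoothFit(
        grid=grid,
        fit=curve,
        band_low=curve - zq * se,
        band_high=curve + zq * se,
        edf=1.0 + edf_nonlin,
        edf_nonlinear=edf_nonlin,
        p_nonlinearity=p_nl,
        lambda_=float(lam),
        covariates=tuple(covariates),
        n_obs=n,
        rss=rss,
        rss_linear=rss_lin,
    )


def stratified_smooths(
    cohort,
    stratum: str,
    exposure: str = "fsh_day7",
    outcome: str = "oocytes",
    covariates=(),
    min_n: int = MIN_COMPLETE_CASES,
    **kwargs,
) -> dict:
    """Independent smooth per stratum level on a shared evaluation grid."""
    df = as_frame(cohort)
    if stratum not in df.columns:
        raise ConfigurationError(f"unknown stratum field {stratum!r}")
    pooled = complete_cases(df, [outcome, exposure, *covariates])
    glo, ghi = np.percentile(pooled[exposure].to_numpy(float), [1, 99])
    grid = np.linspace(glo, ghi, kwargs.pop("grid_size", 200))
    out: dict = {}
    for level in sorted(df[stratum].dropna().unique()):
        sub = df[df[stratum] == level]
        n_cc = len(complete_cases(sub, [outcome, exposure, *covariates]))
        if n_cc < min_n:
            warnings.warn(
                f"stratum {stratum}={level!r}: {n_cc} complete cases < {min_n}; skipped"
            )
            continue
        out[level] = fit_smooth(
            sub, exposure, outcome, covariates, grid=grid, **kwargs
        )
    return out
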