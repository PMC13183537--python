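"""Shared design-matrix construction: complete cases and dummy coding."""

from __future__ import annotations

import numpy as np
import pandas as pd

from fshthreshold.cohort import Cohort
from fshthreshold.exceptions import ConfigurationError


def as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, Cohort):
        return cohort.data
    if isinstance(cohort, pd.DataFrame):
        return cohort
    raise TypeError(f"expected Cohort or DataFrame, got {type(cohort).__name__}")


def is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or (
        pd.api.types.is_string_dtype(s)
    )


def complete_cases(df: pd.DataFrame, columns) -> pd.DataFrame:
    cols = [c for c in columns if c is not None]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"unknown field(s): {missing}")
    return df.dropna(subset=cols)


def reference_level(s: pd.Series, override: str | None = None) -> str:
    """Reference category: the most frequent level unless overridden."""
    if override is not None:
        return override
    return s.value_counts().idxmax()


def dummy_columns(s: pd.Series, name: str, ref: str | None = None):
    """Treatment-coded indicator columns against the reference level."""
    ref = reference_level(s, ref)
    levels = [lv for lv in pd.unique(s.dropna()) if lv != ref]
    levels.sort()
    cols = [(f"{name}[{lv}]", (s == lv).to_numpy(float)) for lv in levels]
    return cols, ref


def covariate_matrix(df: pd.DataFrame, covariates, refs: dict | None = None):
    """Numeric matrix for a covariate list, expanding categoricals.

    Returns ``(Z, names)``; ``Z`` has one column per numeric covariate and
    one per non-reference level of each categorical covariate.
    """
    refs = refs or {}
    cols: list[tuple[str, np.ndarray]] = []
    for c in covariates:
        if c not in df.columns:
            raise ConfigurationError(f"unknown covariate {c!r}")
        s = df[c]
        if is_categorical(s):
            dummies, _ = dummy_columns(s, c, refs.get(c))
            cols.extend(dummies)
        else:
            cols.append((c, s.to_numpy(float)))
    if not cols:
        return np.empty((len(df), 0)), []
    names = [n for n, _ in cols]
    Z = np.column_stack([v for _, v in cols])
    return Z, names
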