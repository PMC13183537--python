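"""Cycle-level cohort container, schema validation, file I/O, and filters.

One row = one controlled-ovarian-stimulation (IVF) cycle.  The exposure is
serum FSH on stimulation Day 7 (mIU/mL), the outcome the number of oocytes
retrieved, and `patient_id` clusters repeated cycles of the same woman.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fshthreshold.exceptions import (
    AmbiguityError,
    ConfigurationError,
    EmptyInputError,
    SchemaError,
    TertileError,
)

SCHEMA_VERSION = "1.0"

INFERTILITY_FACTORS = (
    "tubal",
    "endometriosis",
    "ovulatory",
    "male",
    "unexplained",
    "immune",
    "other",
)
GONADOTROPIN_TYPES = ("recombinant", "urinary")
TERTILE_LABELS = ("low", "medium", "high")

#: column name -> (dtype kind, mandatory)
FLOAT_FIELDS = (
    "fsh_day7",
    "fsh_day1",
    "age",
    "infertility_duration",
    "bmi",
    "amh",
    "initial_dose",
    "total_dose",
)
INT_FIELDS = ("cycle_index", "oocytes", "afc")
BINARY_FIELDS = ("pcos", "por", "canceled")
CATEGORICAL_FIELDS = {
    "infertility_factor": INFERTILITY_FACTORS,
    "gonadotropin_type": GONADOTROPIN_TYPES,
}
MANDATORY_FIELDS = ("patient_id", "fsh_day7", "oocytes")
ALL_FIELDS = (
    ("patient_id",)
    + INT_FIELDS
    + FLOAT_FIELDS
    + BINARY_FIELDS
    + tuple(CATEGORICAL_FIELDS)
)
DERIVED_FIELDS = ("tertile", "first_cycle")

#: header aliases accepted on read (lower-cased comparison)
COLUMN_ALIASES = {
    "id": "patient_id",
    "patient": "patient_id",
    "subject_id": "patient_id",
    "cycle": "cycle_index",
    "cycle_number": "cycle_index",
    "day7_fsh": "fsh_day7",
    "fsh_d7": "fsh_day7",
    "day1_fsh": "fsh_day1",
    "fsh_d1": "fsh_day1",
    "baseline_fsh": "fsh_day1",
    "oocytes_retrieved": "oocytes",
    "n_oocytes": "oocytes",
    "duration": "infertility_duration",
    "infertility_type": "infertility_factor",
    "gn_type": "gonadotropin_type",
    "cancelled": "canceled",
}


@dataclass
class Cohort:
    """Validated collection of cycle records backed by a DataFrame."""

    data: pd.DataFrame
    schema_version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.schema_version)


@dataclass
class ExclusionPolicy:
    """Eligibility policy mirroring the study's flow-chart exclusions.

    Defaults drop canceled cycles and cycles lacking the Day-7 FSH
    measurement; optionally restrict to one gonadotropin type.
    """

    drop_canceled: bool = True
    require_day7_fsh: bool = True
    gonadotropin_type: str | None = None
    extra_required: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.gonadotropin_type is not None and (
            self.gonadotropin_type not in GONADOTROPIN_TYPES
        ):
            raise ConfigurationError(
                f"unknown gonadotropin_type {self.gonadotropin_type!r}; "
                f"valid: {GONADOTROPIN_TYPES}"
            )


def _coerce_numeric(s: pd.Series, kind: str, col: str, strict: bool) -> pd.Series:
    out = pd.to_numeric(s, errors="coerce")
    if strict:
        bad = s.notna() & (s.astype(str).str.strip() != "") & out.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"unparseable value in column {col!r} at row {row}")
    return out.astype(float)


def _validate_frame(df: pd.DataFrame, strict: bool) -> pd.DataFrame:
    """Enforce record invariants; strict mode aborts, lax mode blanks bad cells."""

    def _violation(mask: pd.Series, col: str, what: str):
        if not mask.any():
            return
        if strict:
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise SchemaError(f"invariant violation in {col!r} at row {row}: {what}")
        warnings.warn(
            f"{int(mask.sum())} value(s) in {col!r} violate '{what}'; set to missing",
            stacklevel=3,
        )
        df.loc[mask, col] = np.nan

    if "oocytes" in df:
        _violation(df["oocytes"].notna() & (df["oocytes"] < 0), "oocytes", ">= 0")
    if "fsh_day7" in df:
        _violation(df["fsh_day7"].notna() & (df["fsh_day7"] <= 0), "fsh_day7", "> 0")
    if "cycle_index" in df:
        _violation(
            df["cycle_index"].notna() & (df["cycle_index"] < 1), "cycle_index", ">= 1"
        )
    for col, vocab in CATEGORICAL_FIELDS.items():
        if col in df:
            s = df[col].astype("string").str.strip().str.lower()
            s = s.where(s.notna() & (s != ""), other=pd.NA)
            df[col] = s
            _violation(s.notna() & ~s.isin(vocab), col, f"in {vocab}")
    for col in BINARY_FIELDS:
        if col in df:
            _violation(df[col].notna() & ~df[col].isin((0.0, 1.0)), col, "in {0,1}")
    return df


def validate_cohort(df: pd.DataFrame, strict: bool = False) -> Cohort:
    """Type, normalize, and invariant-check a raw cycle table."""
    if df.empty:
        raise EmptyInputError("cohort table has no rows")
    missing = [c for c in MANDATORY_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in FLOAT_FIELDS:
        if col in df:
            df[col] = _coerce_numeric(df[col], "float", col, strict)
    for col in INT_FIELDS + BINARY_FIELDS:
        if col in df:
            df[col] = _coerce_numeric(df[col], "int", col, strict)
    df = _validate_frame(df, strict)
    if "cycle_index" not in df:
        df["cycle_index"] = 1.0
    return Cohort(df.reset_index(drop=True))


def read_cohort(path, strict: bool = False) -> Cohort:
    """Read a comma-delimited UTF-8 cohort file (header row; missing = empty cell)."""
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty file") from None
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        rename[col] = COLUMN_ALIASES.get(key, key)
    df = df.rename(columns=rename)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return validate_cohort(df, strict=strict)


def write_cohort(cohort: Cohort, path) -> None:
    """Write CSV so that ``read_cohort`` round-trips all finite fields."""
    df = cohort.data.copy()
    # serialize integers without trailing .0 while keeping NaN as empty
    for col in INT_FIELDS + BINARY_FIELDS:
        if col in df:
            df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False, na_rep="")


def apply_exclusions(
    cohort: Cohort, policy: ExclusionPolicy | None = None
) -> tuple[Cohort, dict]:
    """Apply the eligibility policy; return the eligible subset and a count report.

    Counts are sequential (each criterion counts rows removed after the
    previous ones), so they sum to ``n_input - n_eligible``.
    """
    if policy is None:
        policy = ExclusionPolicy()
    df = cohort.data
    report: dict = {"n_input": len(df)}
    keep = pd.Series(True, index=df.index)

    def _step(name: str, mask_drop: pd.Series):
        nonlocal keep
        dropped = int((keep & mask_drop).sum())
        report[name] = dropped
        keep &= ~mask_drop

    if policy.drop_canceled and "canceled" in df:
        _step("canceled", df["canceled"].fillna(0) == 1)
    if policy.require_day7_fsh:
        _step("missing_day7_fsh", df["fsh_day7"].isna())
    if policy.gonadotropin_type is not None:
        if "gonadotropin_type" not in df:
            raise ConfigurationError("policy references absent field gonadotropin_type")
        _step(
            "gonadotropin_type",
            df["gonadotropin_type"].fillna("") != policy.gonadotropin_type,
        )
    for col in policy.extra_required:
        if col not in df:
            raise ConfigurationError(f"policy references unknown field {col!r}")
        _step(f"missing_{col}", df[col].isna())

    out = df[keep].reset_index(drop=True)
    report["n_eligible"] = len(out)
    if len(out) == 0:
        warnings.warn("all records excluded; downstream fitting will refuse this")
    return Cohort(out, cohort.schema_version), report


def assign_tertiles(cohort: Cohort, variable: str = "fsh_day7") -> Cohort:
    """Label records low/medium/high by sample tertiles of ``variable``.

    Cut points are the 1/3 and 2/3 quantiles with linear interpolation
    (quantile type 7); records exactly at a cut go to the lower group
    (closed lower intervals).  Missing values get no label.
    """
    df = cohort.data
    if variable not in df:
        raise ConfigurationError(f"unknown variable {variable!r}")
    v = df[variable].to_numpy(dtype=float)
    finite = v[np.isfinite(v)]
    if np.unique(finite).size < 3:
        raise TertileError(f"{variable!r} has < 3 distinct values")
    q1, q2 = np.quantile(finite, [1 / 3, 2 / 3])  # type-7 interpolation
    lab = np.full(len(df), None, dtype=object)
    ok = np.isfinite(v)
    lab[ok & (v <= q1)] = "low"
    lab[ok & (v > q1) & (v <= q2)] = "medium"
    lab[ok & (v > q2)] = "high"
    out = df.copy()
    out["tertile"] = lab
    return Cohort(out, cohort.schema_version)


def first_cycle_subset(cohort: Cohort) -> Cohort:
    """Keep exactly one record per patient: the one with minimal cycle_index."""
    df = cohort.data
    ci = df["cycle_index"].fillna(1)
    dup = df.assign(_ci=ci).duplicated(subset=["patient_id", "_ci"], keep=False)
    if dup.any():
        pid = df.loc[dup, "patient_id"].iloc[0]
        raise AmbiguityError(f"duplicate (patient_id, cycle_index) pair for {pid!r}")
    idx = ci.groupby(df["patient_id"], sort=False).idxmin()
    out = df.loc[sorted(idx)].reset_index(drop=True)
    out = out.copy()
    out["first_cycle"] = 1
    return Cohort(out, cohort.schema_version)
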