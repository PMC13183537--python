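"""Config-driven end-to-end runs producing a reproducible report bundle.

Stage order mirrors the analysis plan: exclusions -> tertile descriptives ->
univariate screen -> adjusted model + trend test -> smoothing-spline
nonlinearity screen -> segmented-GEE threshold analysis (search, bootstrap
CI, QLR test, cross-validation) -> subgroups -> sensitivity designs.  Every
artifact is regenerable from the config plus the seed; the manifest records
both together with a config hash and package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fshthreshold._version import __version__
from fshthreshold.cohort import (
    Cohort,
    ExclusionPolicy,
    apply_exclusions,
    assign_tertiles,
    read_cohort,
    write_cohort,
)
from fshthreshold.exceptions import ConfigurationError, FshThresholdError
from fshthreshold.gam import fit_smooth
from fshthreshold.screening import (
    baseline_frame,
    baseline_table,
    effects_table,
    trend_test,
    univariate_effects,
    adjusted_effect,
)
from fshthreshold.simulate import default_study_config, simulate_cohort
from fshthreshold.subgroups import (
    DEFAULT_STRATA,
    stratified_effects,
    sensitivity_first_cycle,
    sensitivity_gonadotropin_subset,
    threshold_report,
)
from fshthreshold.threshold import (
    GEESpec,
    SearchConfig,
    cross_validate_threshold,
)

log = logging.getLogger("fshthreshold")

#: the committed study profile: percentile grid 5-95 at step 5, refinement
#: +-4 percentiles at step 1, 1000 bootstrap replicates, 10 CV folds
STUDY_PROFILE = {
    "search": {"grid_start": 5, "grid_stop": 95, "grid_step": 5,
               "refine_halfwidth": 4, "refine_step": 1},
    "bootstrap_B": 1000,
    "cv_folds": 10,
}

DEFAULT_COVARIATES = ("age", "amh", "afc", "fsh_day1", "bmi", "pcos", "por")

UNIVARIATE_EXPOSURES = (
    "age", "infertility_duration", "bmi", "amh", "fsh_day1", "afc",
    "infertility_factor", "por", "pcos", "total_dose", "initial_dose",
)


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    seed: int
    input_path: str | None = None
    simulation: dict | None = None  # kwargs for default_study_config
    output_dir: str = "fshthreshold_run"
    exposure: str = "fsh_day7"
    outcome: str = "oocytes"
    covariates: tuple = DEFAULT_COVARIATES
    exclusion: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    bootstrap_B: int = 1000
    cv_folds: int = 10
    run_gam: bool = True
    run_subgroups: bool = True
    run_sensitivity: bool = True
    working_correlation: str = "exchangeable"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.input_path is None and self.simulation is None:
            self.simulation = {}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, default=str))


def _load_input(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    sim = dict(config.simulation or {})
    sim.setdefault("seed", config.seed)
    cfg = default_study_config(**sim)
    return simulate_cohort(cfg)


def _tertile_models(df, config: RunConfig) -> dict:
    """Crude and adjusted continuous + tertile-dummy models with P for trend."""
    rows = {}
    for label, covs in (("crude", ()), ("adjusted", config.covariates)):
        eff = adjusted_effect(df, config.exposure, config.outcome, covariates=covs)
        rows[label] = {
            "beta": eff.beta, "ci": [eff.ci_low, eff.ci_high],
            "p_value": eff.p_value, "n_used": eff.n_used,
        }
        tert = {}
        for level in ("medium", "high"):
            work = df.assign(_ind=(df["tertile"] == level).astype(float))
            sub = work[work["tertile"].isin(["low", level])]
            e = adjusted_effect(sub, "_ind", config.outcome, covariates=covs)
            tert[level] = {"beta": e.beta, "ci": [e.ci_low, e.ci_high],
                           "p_value": e.p_value}
        rows[label]["tertile_vs_low"] = tert
        rows[label]["p_trend"] = trend_test(
            df, config.outcome, covariates=covs
        )
    return rows


def _plot_curve(sm, path: Path, exposure: str, outcome: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(sm.grid, sm.band_low, sm.band_high, color="#9ecae9",
                    alpha=0.7, label="95% CI")
    ax.plot(sm.grid, sm.fit, color="crimson", lw=2, label="smooth fit")
    ax.set_xlabel(f"{exposure} (mIU/mL)")
    ax.set_ylabel(outcome)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage, writing a bundle to ``config.output_dir``.

    Stage failures are recorded in the manifest and the run continues, so a
    partial bundle with a machine-readable failure record is always produced.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "fshthreshold": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
        "failures": [],
    }
    bundle: dict = {"manifest": manifest}
    spec = GEESpec(working_correlation=config.working_correlation)
    search_cfg = SearchConfig(**config.search)

    def _stage(name, fn):
        try:
            result = fn()
            manifest["stages"].append({"stage": name, "status": "ok"})
            return result
        except FshThresholdError as exc:
            log.warning("stage %s failed: %s", name, exc)
            manifest["failures"].append(
                {"stage": name, "error": str(exc), "error_type": type(exc).__name__}
            )
            manifest["stages"].append({"stage": name, "status": "failed"})
            return None

    cohort = _stage("input", lambda: _load_input(config))
    if cohort is None:
        _write_json(out / "manifest.json", manifest)
        return bundle
    if config.input_path is None:
        write_cohort(cohort, out / "cohort.csv")

    policy = ExclusionPolicy(**config.exclusion)
    res = _stage("exclusions", lambda: apply_exclusions(cohort, policy))
    if res is None:
        _write_json(out / "manifest.json", manifest)
        return bundle
    eligible, excl_report = res
    log.info("exclusions: %s", excl_report)
    bundle["exclusions"] = excl_report
    _write_json(out / "exclusion_report.json", excl_report)

    tert = _stage("tertiles", lambda: assign_tertiles(eligible, config.exposure))
    if tert is not None:
        eligible = tert
        t1 = _stage("baseline_table", lambda: baseline_table(eligible))
        if t1 is not None:
            baseline_frame(t1).to_csv(out / "table1_baseline.csv", index=False)
            bundle["baseline"] = t1

    t2 = _stage(
        "univariate_screen",
        lambda: univariate_effects(
            eligible,
            config.outcome,
            [e for e in UNIVARIATE_EXPOSURES if e in eligible.data.columns],
        ),
    )
    if t2 is not None:
        effects_table(t2).to_csv(out / "table2_univariate.csv", index=False)
        bundle["univariate"] = t2

    t3 = _stage("adjusted_model", lambda: _tertile_models(eligible.data, config))
    if t3 is not None:
        _write_json(out / "table3_adjusted.json", t3)
        bundle["adjusted"] = t3

    if config.run_gam:
        sm = _stage(
            "gam_screen",
            lambda: fit_smooth(
                eligible, config.exposure, config.outcome, config.covariates
            ),
        )
        if sm is not None:
            sm.to_frame().to_csv(out / "smooth_curve.csv", index=False)
            _stage("gam_plot", lambda: _plot_curve(
                sm, out / "smooth_curve.png", config.exposure, config.outcome))
            bundle["gam"] = {"edf": sm.edf, "p_nonlinearity": sm.p_nonlinearity}

    def _threshold():
        rep = threshold_report(
            eligible,
            config.covariates,
            spec,
            search_cfg,
            bootstrap_B=config.bootstrap_B,
            seed=config.seed,
            exposure=config.exposure,
            outcome=config.outcome,
            run_gam=False,
        )
        if rep.get("status") != "ok":
            raise ConfigurationError(
                f"threshold stage failed at {rep.get('stage')}: {rep.get('error')}"
            )
        return rep

    thr = _stage("threshold", _threshold)
    if thr is not None:
        _write_json(out / "table4_threshold.json", thr)
        if thr.get("profile"):
            pd.DataFrame(thr["profile"]).to_csv(
                out / "ql_profile.csv", index=False
            )
        bundle["threshold"] = thr

    if config.cv_folds and thr is not None:
        cv = _stage(
            "cross_validation",
            lambda: cross_validate_threshold(
                eligible, config.covariates, spec, search_cfg,
                folds=config.cv_folds, seed=config.seed,
                exposure=config.exposure, outcome=config.outcome,
            ),
        )
        if cv is not None:
            _write_json(out / "cv_summary.json", cv)
            bundle["cv"] = cv

    if config.run_subgroups:
        sg = _stage(
            "subgroups",
            lambda: stratified_effects(
                eligible,
                [d for d in DEFAULT_STRATA if d.variable in eligible.data.columns],
                config.exposure,
                config.outcome,
                config.covariates,
            ),
        )
        if sg is not None:
            rows = []
            for r in sg:
                for lab in r.labels:
                    e = r.effects.get(lab)
                    rows.append({
                        "variable": r.variable, "stratum": lab,
                        "n": r.n_per_stratum[lab],
                        "beta": e.beta if e else None,
                        "ci_low": e.ci_low if e else None,
                        "ci_high": e.ci_high if e else None,
                        "p_value": e.p_value if e else None,
                        "p_interaction": r.p_interaction,
                    })
            pd.DataFrame(rows).to_csv(out / "table5_subgroups.csv", index=False)
            bundle["subgroups"] = sg

    if config.run_sensitivity:
        fc = _stage(
            "sensitivity_first_cycle",
            lambda: sensitivity_first_cycle(
                eligible, config.covariates, spec, search_cfg,
                bootstrap_B=config.bootstrap_B, seed=config.seed,
                exposure=config.exposure, outcome=config.outcome,
            ),
        )
        if fc is not None:
            _write_json(out / "sensitivity_first_cycle.json", fc)
            bundle["sensitivity_first_cycle"] = fc
        types = set(eligible.data.get("gonadotropin_type", pd.Series(dtype=object)).dropna())
        if len(types) > 1:
            for gn in sorted(types):
                rep = _stage(
                    f"sensitivity_gonadotropin_{gn}",
                    lambda gn=gn: sensitivity_gonadotropin_subset(
                        eligible, gn, config.covariates, spec, search_cfg,
                        bootstrap_B=config.bootstrap_B, seed=config.seed,
                        exposure=config.exposure, outcome=config.outcome,
                    ),
                )
                if rep is not None:
                    _write_json(out / f"sensitivity_gonadotropin_{gn}.json", rep)
                    bundle[f"sensitivity_gonadotropin_{gn}"] = rep

    _write_json(out / "manifest.json", manifest)
    return bundle
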