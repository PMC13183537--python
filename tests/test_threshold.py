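"""Segmented-GEE threshold machinery: basis, search, bootstrap, QLR, CV."""

import numpy as np
import pandas as pd
import pytest

from fshthreshold import (
    bootstrap_breakpoint_ci,
    cross_validate_threshold,
    default_study_config,
    fit_segmented_gee,
    hinge_design,
    qlr_threshold_test,
    recursive_threshold_search,
    simulate_cohort,
)
from fshthreshold.exceptions import (
    CollinearityError,
    ComparisonError,
    ConfigurationError,
    SearchError,
)
from fshthreshold.gee import cluster_blocks, fit_gee
from fshthreshold.threshold import (
    GEESpec,
    SearchConfig,
    _design_segmented,
    _prepare,
)

COVS = ("age", "amh", "afc", "fsh_day1", "bmi", "pcos", "por")


class TestHingeDesign:
    @pytest.mark.parametrize(
        "fsh,expected",
        [(9.13, (0.0, 0.0)), (10.13, (0.0, 1.0)), (8.13, (-1.0, 0.0))],
    )
    def test_anchor_and_unit_steps(self, fsh, expected):
        below, above = hinge_design([fsh], 9.13)
        assert (below[0], above[0]) == pytest.approx(expected)

    def test_columns_sum_to_centered_exposure(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(2, 30, 500)
        below, above = hinge_design(f, 11.0)
        assert np.allclose(below + above, f - 11.0)


class TestSegmentedFit:
    def test_reparameterization_identity(self, study_cohort_small):
        """Basis {FSH, (FSH-K)[FSH>=K]} gives beta_below = beta1 and
        beta_below + slope-change = beta1 + (beta2-beta1) = hinge beta2."""
        K = 9.13
        fit = fit_segmented_gee(study_cohort_small, K, COVS)
        d = _prepare(study_cohort_small, "fsh_day7", "oocytes", COVS, GEESpec())
        _, above = hinge_design(d["fsh"], K)
        X = np.column_stack([np.ones(len(d["y"])), d["fsh"], above, d["Z"]])
        alt = fit_gee(d["y"], X, d["starts"], d["sizes"])
        assert alt.beta[1] == pytest.approx(fit.beta1, abs=1e-8)
        assert alt.beta[1] + alt.beta[2] == pytest.approx(fit.beta2, abs=1e-8)

    def test_outcome_shift_invariance(self, study_cohort_small):
        fit = fit_segmented_gee(study_cohort_small, 9.13, COVS)
        shifted = study_cohort_small.data.copy()
        shifted["oocytes"] = shifted["oocytes"] + 5.0
        fit2 = fit_segmented_gee(shifted, 9.13, COVS)
        assert fit2.beta0 == pytest.approx(fit.beta0 + 5.0, abs=1e-7)
        assert fit2.beta1 == pytest.approx(fit.beta1, abs=1e-8)
        assert fit2.beta2 == pytest.approx(fit.beta2, abs=1e-8)

    def test_k_outside_range_rejected(self, study_cohort_small):
        with pytest.raises(ConfigurationError, match="strictly inside"):
            fit_segmented_gee(study_cohort_small, 1000.0, COVS)

    def test_cis_bracket_estimates(self, study_cohort_small):
        fit = fit_segmented_gee(study_cohort_small, 9.13, COVS)
        for name in fit.names:
            lo, hi = fit.ci[name]
            assert lo <= hi


class TestRecursiveSearch:
    def test_kopt_attains_max_over_trace(self, study_cohort_small):
        res = recursive_threshold_search(study_cohort_small, COVS)
        evaluated = [r for r in res.trace if not r["skipped"]]
        best_ql = max(r["ql"] for r in evaluated)
        winners = [r["K"] for r in evaluated if r["ql"] == best_ql]
        assert res.K_opt == min(winners)
        assert res.fit.K == res.K_opt

    def test_noiseless_truth_on_grid_is_recovered(self):
        cfg = default_study_config(
            n_patients=700, seed=2, sigma=0.0, round_and_clip=False
        )
        fsh = simulate_cohort(cfg).data["fsh_day7"].to_numpy()
        grid = np.percentile(fsh, np.arange(5, 96))
        kstar = float(grid[np.argmin(np.abs(grid - 9.13))])
        c = simulate_cohort(
            default_study_config(
                n_patients=700, seed=2, sigma=0.0, round_and_clip=False, true_K=kstar
            )
        )
        res = recursive_threshold_search(c, COVS)
        assert res.K_opt == kstar

    def test_min_segment_guard_skips_candidates(self, study_cohort_small):
        cfg = SearchConfig(min_segment=10_000)
        with pytest.raises(SearchError):
            recursive_threshold_search(study_cohort_small, COVS, config=cfg)

    def test_linear_truth_gives_flat_profile_and_null_qlr(self):
        cfg = default_study_config(
            n_patients=1500, seed=5, beta1=-0.07, beta2=-0.07, round_and_clip=False
        )
        c = simulate_cohort(cfg)
        res = recursive_threshold_search(c, COVS)
        qlr = qlr_threshold_test(c, res.fit, COVS)
        evaluated = [r["ql"] for r in res.trace if not r["skipped"]]
        # profile spread is tiny relative to the quasi-likelihood scale
        assert (max(evaluated) - min(evaluated)) < 0.02 * abs(np.mean(evaluated))
        assert qlr["p_value"] > 1e-4


class TestBootstrap:
    def test_seed_determinism(self, study_cohort_small):
        a = bootstrap_breakpoint_ci(study_cohort_small, COVS, B=40, seed=123)
        b = bootstrap_breakpoint_ci(study_cohort_small, COVS, B=40, seed=123)
        assert a == b
        assert a[0] <= a[1]

    def test_noiseless_ci_degenerates_to_grid_neighborhood(self):
        cfg = default_study_config(
            n_patients=600, seed=8, sigma=0.0, round_and_clip=False
        )
        c = simulate_cohort(cfg)
        (lo, hi), ks = bootstrap_breakpoint_ci(
            c, COVS, B=60, seed=1, return_replicates=True
        )
        # every replicate pins the breakpoint next to the true kink
        assert hi - lo < 0.2
        assert abs(np.median(ks) - 9.13) < 0.2


class TestQlr:
    def test_row_mismatch_raises(self, study_cohort_small):
        fit = fit_segmented_gee(study_cohort_small, 9.13, COVS)
        with pytest.raises(ComparisonError):
            qlr_threshold_test(study_cohort_small.data.iloc[:-5], fit, COVS)

    def test_strong_kink_is_significant(self, study_cohort_small):
        res = recursive_threshold_search(study_cohort_small, COVS)
        qlr = qlr_threshold_test(study_cohort_small, res.fit, COVS)
        assert qlr["p_value"] < 1e-6
        assert qlr["statistic"] >= 0 and qlr["df"] == 1


class TestCrossValidation:
    def test_determinism_and_fold_structure(self, study_cohort_small):
        cv1 = cross_validate_threshold(study_cohort_small, COVS, folds=5, seed=3)
        cv2 = cross_validate_threshold(study_cohort_small, COVS, folds=5, seed=3)
        assert cv1 == cv2
        assert len(cv1["per_fold"]) == 5
        n_test = sum(r["n_test"] for r in cv1["per_fold"])
        assert n_test == len(study_cohort_small.data)

    def test_segmented_beats_linear_under_kink(self, study_cohort_small):
        cv = cross_validate_threshold(study_cohort_small, COVS, folds=5, seed=3)
        assert cv["pooled_mse_segmented"] < cv["pooled_mse_linear"]
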