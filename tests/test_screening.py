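"""Group-comparison tables, univariate/adjusted linear screens, trend test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fshthreshold import (
    adjusted_effect,
    assign_tertiles,
    baseline_table,
    trend_test,
    univariate_effects,
)
from fshthreshold.cohort import validate_cohort
from fshthreshold.exceptions import CollinearityError, StratumError

from conftest import make_cycle_frame


def _tertiled(df):
    return assign_tertiles(validate_cohort(df))


class TestBaselineTable:
    def test_chi_square_matches_hand_formula_on_reported_counts(self):
        """Contingency-table statistic equals the textbook sum((O-E)^2/E)
        computed from the reference per-tertile case counts."""
        counts = {"low": 1112, "medium": 132, "high": 13}
        per_group = 3323
        rows = []
        for g, k in counts.items():
            rows.append(pd.DataFrame({"pcos": [1.0] * k + [0.0] * (per_group - k),
                                      "tertile": g}))
        df = pd.concat(rows, ignore_index=True)
        df["patient_id"] = np.arange(len(df)).astype(str)
        df["fsh_day7"] = {"low": 8.0, "medium": 13.0, "high": 19.0}  # placeholder
        df["fsh_day7"] = df["tertile"].map({"low": 8.0, "medium": 13.0, "high": 19.0})
        df["oocytes"] = 1.0
        df["pcos_flag"] = df["pcos"].map({1.0: "yes", 0.0: "no"})
        c = validate_cohort(df)
        table = baseline_table(c, variables=["pcos_flag"])
        observed = np.array([[counts[g], per_group - counts[g]]
                             for g in ("low", "medium", "high")]).T
        expected = observed.sum(1, keepdims=True) * observed.sum(0) / observed.sum()
        hand = float(((observed - expected) ** 2 / expected).sum())
        assert table[0].statistic == pytest.approx(hand, abs=1e-6)
        assert table[0].test == "chi_square"

    def test_identical_proportions_give_zero_statistic(self):
        df = make_cycle_frame(60, patient_id=np.arange(60))
        df["tertile"] = ["low", "medium", "high"] * 20
        df["flag"] = (["yes"] * 3 + ["no"] * 3) * 10
        c = validate_cohort(df)
        c.data["tertile"] = df["tertile"].to_numpy()
        row = baseline_table(c, variables=["flag"])[0]
        assert row.statistic == pytest.approx(0.0, abs=1e-12)
        assert row.p_value == pytest.approx(1.0)

    def test_anova_on_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(4)
        df = make_cycle_frame(80, patient_id=np.arange(80))
        df["tertile"] = ["low"] * 40 + ["medium"] * 40
        df["marker"] = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.4, 1, 40)])
        c = validate_cohort(df)
        c.data["tertile"] = df["tertile"].to_numpy()
        row = [r for r in baseline_table(c, variables=["marker"]) if r.test == "anova"][0]
        t, _ = stats.ttest_ind(df["marker"][:40], df["marker"][40:])
        assert row.statistic == pytest.approx(t**2, rel=1e-10)

    def test_skewed_variable_uses_kruskal_wallis(self):
        rng = np.random.default_rng(5)
        df = make_cycle_frame(90, patient_id=np.arange(90))
        df["amh"] = rng.lognormal(0.5, 1.2, 90)  # heavy right skew
        c = _tertiled(df)
        row = [r for r in baseline_table(c, variables=["amh"])][0]
        assert row.test == "kruskal_wallis"

    def test_empty_group_raises(self):
        df = make_cycle_frame(10, patient_id=np.arange(10))
        df["tertile"] = "low"
        c = validate_cohort(df)
        c.data["tertile"] = "low"
        with pytest.raises(StratumError):
            baseline_table(c, variables=["age"])


class TestUnivariate:
    def test_perfect_fit_has_zero_width_ci(self):
        df = make_cycle_frame(10, patient_id=np.arange(10))
        df["oocytes"] = 2.0 * df["fsh_day7"]
        eff = univariate_effects(validate_cohort(df), exposures=["fsh_day7"])[0]
        assert eff.beta == pytest.approx(2.0, abs=1e-10)
        assert eff.ci_high - eff.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_recovers_simulated_slope_within_sampling_bounds(self):
        rng = np.random.default_rng(6)
        n = 10_000
        x = rng.uniform(0, 10, n)
        df = make_cycle_frame(n, patient_id=np.arange(n), fsh_day7=x)
        df["oocytes"] = 13 - 0.5 * x + rng.normal(0, 1, n)
        eff = univariate_effects(df, exposures=["fsh_day7"])[0]
        assert -0.53 <= eff.beta <= -0.47

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        df = make_cycle_frame(n, patient_id=np.arange(n), fsh_day7=np.abs(x) + 1)
        df["oocytes"] = y
        eff = univariate_effects(df, exposures=["fsh_day7"])[0]
        X = np.column_stack([np.ones(n), np.abs(x) + 1])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert eff.beta == pytest.approx(oracle[1], abs=1e-10)

    def test_categorical_exposure_expands_against_reference(self):
        df = make_cycle_frame(90, patient_id=np.arange(90))
        df["infertility_factor"] = ["tubal"] * 60 + ["male"] * 20 + ["other"] * 10
        effs = univariate_effects(
            validate_cohort(df), exposures=["infertility_factor"]
        )
        assert {e.level for e in effs} == {"male", "other"}  # tubal = reference

    def test_constant_exposure_skipped_with_warning(self):
        df = make_cycle_frame(20, patient_id=np.arange(20))
        df["initial_dose"] = 150.0
        with pytest.warns(UserWarning, match="constant"):
            effs = univariate_effects(
                validate_cohort(df), exposures=["initial_dose", "fsh_day7"]
            )
        assert [e.exposure for e in effs] == ["fsh_day7"]


class TestAdjusted:
    def test_no_covariates_reduces_to_univariate(self, study_cohort_small):
        uni = univariate_effects(study_cohort_small, exposures=["fsh_day7"])[0]
        adj = adjusted_effect(study_cohort_small, "fsh_day7", covariates=())
        assert adj.beta == pytest.approx(uni.beta, abs=1e-12)
        assert adj.p_value == pytest.approx(uni.p_value, abs=1e-12)

    def test_adjustment_removes_confounding(self):
        rng = np.random.default_rng(7)
        n = 8000
        u = rng.normal(size=n)
        x = u + rng.normal(size=n)  # exposure confounded by u
        y = 1.0 * u + 0.2 * x + rng.normal(size=n)  # direct effect 0.2
        df = make_cycle_frame(n, patient_id=np.arange(n), fsh_day7=x + 10)
        df["oocytes"] = y + 10  # keep counts positive; intercept shift only
        df["amh"] = u
        crude = univariate_effects(df, exposures=["fsh_day7"])[0]
        adj = adjusted_effect(df, "fsh_day7", covariates=("amh",))
        assert abs(adj.beta - 0.2) < 0.05
        assert crude.beta > 0.4  # crude estimate absorbs the confounder

    def test_duplicated_covariate_raises_collinearity(self, study_cohort_small):
        df = study_cohort_small.data.copy()
        df["age_copy"] = df["age"]
        with pytest.raises(CollinearityError):
            adjusted_effect(df, "fsh_day7", covariates=("age", "age_copy"))

    def test_ci_sign_duality(self, study_cohort_small):
        for cov in ((), ("age", "amh")):
            e = adjusted_effect(study_cohort_small, "fsh_day7", covariates=cov)
            excludes_zero = e.ci_low > 0 or e.ci_high < 0
            assert excludes_zero == (e.p_value < 0.05)


class TestTrend:
    def test_strong_trend_detected(self):
        rng = np.random.default_rng(8)
        n = 3000
        df = make_cycle_frame(n, patient_id=np.arange(n),
                              fsh_day7=rng.uniform(4, 25, n))
        c = _tertiled(df)
        score = c.data["tertile"].map({"low": 1, "medium": 2, "high": 3})
        c.data["oocytes"] = 2.0 * score + rng.normal(0, 1, n)
        assert trend_test(c) < 1e-6

    def test_null_trend_not_significant_typically(self):
        rng = np.random.default_rng(9)
        pvals = []
        for rep in range(40):
            n = 300
            df = make_cycle_frame(n, patient_id=np.arange(n),
                                  fsh_day7=rng.uniform(4, 25, n))
            df["oocytes"] = rng.normal(10, 3, n)
            pvals.append(trend_test(_tertiled(df)))
        assert 0.0 <= np.mean(np.array(pvals) < 0.05) <= 0.15
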