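import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hte_emulate.design import design_matrix
from hte_emulate.ensemble import LearnerSpec, cv_stack
from hte_emulate.gcomputation import (
    CounterfactualPredictions,
    baseline_table,
    compute_ite,
    counterfactual_predict,
    estimate_effects,
    evalue_rr,
    nnt_from_rd,
    propensity_overlap,
)
from hte_emulate.generate import generate_cohort, randomized_config
from hte_emulate.schema import Covariate, CovariateSchema

from .test_ensemble import _stub_model


class TestCounterfactualPredict:
    def test_constant_learner_gives_equal_arms(self):
        X = pd.DataFrame({"x": [0.0, 1.0], "treatment": [0.0, 1.0]})
        model = _stub_model([0.3], [1.0], ["x", "treatment"])
        cf = counterfactual_predict(model, X)
        np.testing.assert_allclose(cf.p1, 0.3)
        np.testing.assert_allclose(cf.p0, 0.3)

    def test_saturated_logistic_recovers_cell_proportions(self):
        # deterministic 2x2 layout: outcome proportions fixed per (x, A) cell
        rows = []
        for x, a, p_cell, n_cell in [
            (0, 0, 0.2, 50),
            (0, 1, 0.4, 50),
            (1, 0, 0.6, 50),
            (1, 1, 0.3, 50),
        ]:
            n1 = int(round(p_cell * n_cell))
            rows += [(x, a, 1)] * n1 + [(x, a, 0)] * (n_cell - n1)
        df = pd.DataFrame(rows, columns=["x", "treatment", "y"])
        X = df[["x", "treatment"]].astype(float)
        y = df["y"].to_numpy(dtype=float)
        model = cv_stack(
            X, y, library=[LearnerSpec("sat", "glm", {"treatment_interactions": True, "C": 1e6})],
            V=5, seed=0,
        )
        cf = counterfactual_predict(model, X)
        cell = df.groupby(["x", "treatment"])["y"].mean()
        for xv in (0, 1):
            rows_x = X["x"] == xv
            assert cf.p1[rows_x].mean() == pytest.approx(cell[(xv, 1)], abs=2e-3)
            assert cf.p0[rows_x].mean() == pytest.approx(cell[(xv, 0)], abs=2e-3)


class TestIte:
    def test_subtraction_and_linearity(self):
        cf = CounterfactualPredictions(
            p1=np.array([0.2, 0.5]), p0=np.array([0.3, 0.5]), outcome_kind="binary"
        )
        ite = compute_ite(cf)
        np.testing.assert_allclose(ite.ite, [-0.1, 0.0])
        assert ite.ate == pytest.approx(cf.p1.mean() - cf.p0.mean())

    def test_binary_predictions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            CounterfactualPredictions(np.array([0.0]), np.array([0.5]), "binary")


class TestSummaryTransforms:
    @pytest.mark.parametrize(
        "rd,expected", [(0.052, 19.2), (0.044, 22.7), (0.17, 5.9), (0.15, 6.7), (1.0, 1.0)]
    )
    def test_nnt_printed_values(self, rd, expected):
        assert round(nnt_from_rd(rd), 1) == expected

    def test_nnt_zero_rd_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            nnt_from_rd(0.0)

    @given(st.floats(min_value=1e-4, max_value=0.9))
    @settings(max_examples=50, deadline=None)
    def test_nnt_reciprocal_identity(self, rd):
        assert nnt_from_rd(rd) * abs(rd) == pytest.approx(1.0)

    @pytest.mark.parametrize("rr,expected", [(0.81, 1.77), (0.41, 4.31), (1.35, 2.04), (1.0, 1.0)])
    def test_evalue_printed_values(self, rr, expected):
        assert round(evalue_rr(rr), 2) == expected

    @pytest.mark.parametrize("rr", [0.0, -1.0, np.inf])
    def test_evalue_invalid_rr_rejected(self, rr):
        with pytest.raises(ValueError):
            evalue_rr(rr)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_evalue_reciprocal_symmetry(self, rr):
        assert evalue_rr(rr) == pytest.approx(evalue_rr(1.0 / rr), rel=1e-9)


class TestEstimateEffects:
    def test_equal_arms_give_null_point_estimates(self):
        n = 40
        X = pd.DataFrame({"x": np.linspace(0, 1, n), "treatment": [0.0, 1.0] * (n // 2)})
        y = np.array([0.0, 1.0] * (n // 2))
        model = _stub_model([0.3], [1.0], ["x", "treatment"])
        model.oof_predictions = np.full((n, 1), 0.3)
        out = estimate_effects(X, y, model=model, n_boot=20, seed=0, fast_boot=True)
        assert out["ATE"].point == pytest.approx(0.0, abs=1e-12)
        assert out["RR"].point == pytest.approx(1.0, abs=1e-12)

    def test_point_ate_equals_mean_ite(self, schema, small_design):
        X, y = small_design
        model = cv_stack(X, y, library=[LearnerSpec("glm", "glm")], V=5, seed=0)
        out = estimate_effects(X, y, model=model, n_boot=10, seed=0, fast_boot=True)
        ite = compute_ite(counterfactual_predict(model, X))
        assert out["ATE"].point == pytest.approx(ite.ate, abs=1e-15)
        assert out["RR"].point == pytest.approx(
            float(np.mean(counterfactual_predict(model, X).p1))
            / float(np.mean(counterfactual_predict(model, X).p0)),
            abs=1e-12,
        )
        assert out["ATE"].ci_low <= out["ATE"].point <= out["ATE"].ci_high

    def test_ate_recovery_under_randomization(self, schema):
        cfg = randomized_config(n_total=6000, seed=31, treatment_main_effect=-0.4)
        table, oracle = generate_cohort(cfg, schema)
        X = design_matrix(table, schema)
        y = table["y_uncontrolled"].to_numpy(dtype=float)
        model = cv_stack(
            X, y, library=[LearnerSpec("glm_tx", "glm", {"treatment_interactions": True})],
            V=5, seed=31,
        )
        ite = compute_ite(counterfactual_predict(model, X))
        # single-replicate Monte-Carlo bound: ~3 x SE of a two-arm risk
        # difference at n=6000 with ~30% outcome prevalence
        se = np.sqrt(2 * 0.3 * 0.7 / 3000)
        assert abs(ite.ate - oracle.true_ate) < 3 * se

    def test_null_effect_ci_coverage(self, schema):
        """Percentile-bootstrap CI covers the null in most randomized-null runs."""
        covered = 0
        n_runs = 25
        lib = [LearnerSpec("glm", "glm")]
        for seed in range(n_runs):
            cfg = randomized_config(n_total=600, seed=400 + seed, treatment_main_effect=0.0)
            table, _ = generate_cohort(cfg, schema)
            X = design_matrix(table, schema)
            y = table["y_uncontrolled"].to_numpy(dtype=float)
            out = estimate_effects(X, y, library=lib, V=3, n_boot=60, seed=seed)
            if out["ATE"].ci_low <= 0.0 <= out["ATE"].ci_high:
                covered += 1
        assert covered >= 0.8 * n_runs

    def test_single_arm_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0], "treatment": [1.0, 1.0]})
        with pytest.raises(ValueError, match="both treatment arms"):
            estimate_effects(X, np.array([0.0, 1.0]), n_boot=5, seed=0)


class TestPropensityOverlap:
    def test_random_assignment_concentrates_near_rate(self, schema, small_cohort):
        table, _ = small_cohort
        X = design_matrix(table, schema, include_treatment=False)
        A = table["treatment"].to_numpy()
        rep = propensity_overlap(X, A, V=4, seed=0)
        rate = A.mean()
        assert abs(rep["treated"]["q50"] - rate) < 0.1
        assert abs(rep["control"]["q50"] - rate) < 0.1
        assert not rep["separation_warning"]

    def test_overlap_interval_inside_unit_interval(self, schema, small_cohort):
        table, _ = small_cohort
        X = design_matrix(table, schema, include_treatment=False)
        rep = propensity_overlap(X, table["treatment"].to_numpy(), V=4, seed=1)
        lo, hi = rep["overlap_interval"]
        assert 0.0 <= lo <= hi <= 1.0

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(0)
        A = np.array([0] * 50 + [1] * 50)
        X = pd.DataFrame({"x": A * 10.0 + rng.normal(0, 0.01, 100)})
        rep = propensity_overlap(X, A, V=4, seed=0)
        assert rep["separation_warning"]


class TestBaselineTable:
    def _mini_schema(self):
        return CovariateSchema((Covariate("sex_male", "binary"), Covariate("age", "continuous")))

    def test_printed_two_by_two_split_is_significant(self):
        # male/female counts by arm: 1767/1198 control, 99/28 treated
        sex = [1.0] * 1767 + [0.0] * 1198 + [1.0] * 99 + [0.0] * 28
        arm = [0] * 2965 + [1] * 127
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"sex_male": sex, "treatment": arm, "age": rng.normal(50, 8, 3092)})
        tab = baseline_table(df, self._mini_schema())
        row = tab[(tab["covariate"] == "sex_male") & (tab["level"] == "yes")].iloc[0]
        assert row["p_value"] < 0.01
        assert row["p_display"] == "< 0.01"
        assert row["control_n"] == 1767 and row["treated_n"] == 99

    def test_missing_counts_match_mask(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "sex_male": rng.integers(0, 2, 200).astype(float),
                "age": rng.normal(50, 8, 200),
                "treatment": rng.integers(0, 2, 200),
            }
        )
        df.loc[:9, "sex_male"] = np.nan
        tab = baseline_table(df, self._mini_schema())
        miss = tab[(tab["covariate"] == "sex_male") & (tab["level"] == "Missing")].iloc[0]
        expected = df[df["sex_male"].isna()].groupby("treatment").size()
        assert miss["control_n"] == expected.get(0, 0)
        assert miss["treated_n"] == expected.get(1, 0)

    def test_continuous_rows_report_mean_sd(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "sex_male": rng.integers(0, 2, 300).astype(float),
                "age": rng.normal(50, 8, 300),
                "treatment": rng.integers(0, 2, 300),
            }
        )
        tab = baseline_table(df, self._mini_schema())
        row = tab[tab["covariate"] == "age"].iloc[0]
        ctrl = df.loc[df["treatment"] == 0, "age"]
        assert row["control_mean"] == pytest.approx(ctrl.mean())
        assert row["control_sd"] == pytest.approx(ctrl.std(ddof=1))
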