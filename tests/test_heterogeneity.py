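import numpy as np
import pandas as pd
import pytest

from hte_emulate.gcomputation import CounterfactualPredictions, ITEVector
from hte_emulate.generate import generate_cohort, recovery_config
from hte_emulate.heterogeneity import (
    beale_select_k,
    cluster_cate,
    cluster_profile,
    covariate_importance,
    jitter_standardize,
    sensitivity_thresholds,
    ward_cluster,
)
from hte_emulate.schema import Covariate, CovariateSchema


class TestJitterStandardize:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_moments_exact(self, seed):
        rng = np.random.default_rng(seed)
        z = jitter_standardize(rng.normal(-0.05, 0.07, 500), seed=seed)
        assert abs(z.z_ite.mean()) < 1e-9
        assert abs(np.std(z.z_ite) - 0.1) < 1e-9

    def test_three_point_worked_example(self):
        z = jitter_standardize(np.array([-0.2, 0.0, 0.2]), noise_sd=0.0, seed=0)
        np.testing.assert_allclose(z.z_ite, [-0.12247449, 0.0, 0.12247449], atol=1e-8)

    def test_deterministic_under_seed(self):
        x = np.linspace(-0.1, 0.1, 50)
        z1 = jitter_standardize(x, seed=5)
        z2 = jitter_standardize(x, seed=5)
        np.testing.assert_array_equal(z1.z_ite, z2.z_ite)

    def test_constant_input_without_noise_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            jitter_standardize(np.zeros(20), noise_sd=0.0, seed=0)


def naive_ward_d2(x: np.ndarray):
    """Brute-force O(n^3) agglomerative Ward (squared-increment distance).

    Cluster distance sqrt(2 |A||B| / (|A|+|B|)) * |mean_A - mean_B| in one
    dimension; returns merge heights and the merged member sets.
    """
    clusters = [frozenset([i]) for i in range(len(x))]
    heights, merged_sets = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = np.array([x[m] for m in clusters[i]])
                b = np.array([x[m] for m in clusters[j]])
                d = np.sqrt(2 * len(a) * len(b) / (len(a) + len(b))) * abs(a.mean() - b.mean())
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        new = clusters[i] | clusters[j]
        heights.append(d)
        merged_sets.append(new)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [new]
    return heights, merged_sets


class TestWardCluster:
    def test_two_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-0.1, 0.005, 50), rng.normal(0.1, 0.005, 50)])
        sol = ward_cluster(x)
        labels = sol.labels_for_k(2)
        assert len(np.unique(labels[:50])) == 1
        assert len(np.unique(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        sol = ward_cluster(rng.normal(0, 0.1, 80))
        h = sol.linkage[:, 2]
        assert np.all(np.diff(h) >= -1e-12)

    def test_agreement_with_naive_oracle_on_twelve_points(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 12)
        sol = ward_cluster(x)
        heights, merged_sets = naive_ward_d2(x)
        np.testing.assert_allclose(np.sort(sol.linkage[:, 2]), np.sort(heights), rtol=1e-10)
        # reconstruct scipy's merged member sets
        n = 12
        members = {i: frozenset([i]) for i in range(n)}
        scipy_sets = []
        for row_i, (a, b, _, _) in enumerate(sol.linkage):
            new = members[int(a)] | members[int(b)]
            members[n + row_i] = new
            scipy_sets.append(new)
        assert set(scipy_sets) == set(merged_sets)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            ward_cluster(np.arange(5, dtype=float))


class TestBealeSelectK:
    @staticmethod
    def _fit(x):
        z = jitter_standardize(x, noise_sd=0.0, seed=1)
        return beale_select_k(z, ward_cluster(z))

    def test_two_well_separated_gaussians_give_two(self):
        rng = np.random.default_rng(0)
        sol = self._fit(np.concatenate([rng.normal(-0.1, 0.01, 100), rng.normal(0.1, 0.01, 100)]))
        assert sol.k == 2
        assert not sol.no_significant_structure

    def test_three_well_separated_gaussians_give_three(self):
        rng = np.random.default_rng(0)
        sol = self._fit(
            np.concatenate(
                [rng.normal(-0.2, 0.01, 80), rng.normal(0.0, 0.01, 80), rng.normal(0.2, 0.01, 80)]
            )
        )
        assert sol.k == 3

    def test_single_gaussian_floors_at_two_with_flag(self):
        rng = np.random.default_rng(0)
        sol = self._fit(rng.normal(0.0, 0.05, 200))
        assert sol.k == 2
        assert sol.no_significant_structure

    def test_path_covers_transitions_and_respects_alpha(self):
        rng = np.random.default_rng(3)
        sol = self._fit(np.concatenate([rng.normal(-0.1, 0.01, 60), rng.normal(0.1, 0.01, 60)]))
        transitions = [e["transition"] for e in sol.beale_path]
        assert transitions[0] == "1->2"
        assert all(e["alpha"] == 0.01 for e in sol.beale_path)


class TestCovariateImportance:
    def _schema(self):
        return CovariateSchema(
            (Covariate("v", "continuous"), Covariate("flat", "continuous"))
        )

    def test_hand_computed_two_cluster_importance(self):
        table = pd.DataFrame({"v": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0], "flat": np.ones(6)})
        labels = np.array([1, 1, 1, 2, 2, 2])
        imp = covariate_importance(table, self._schema(), labels)
        row = imp.table.set_index("variable").loc["v"]
        assert row["z_cluster_1"] == pytest.approx(-1.0)
        assert row["z_cluster_2"] == pytest.approx(1.0)
        assert row["importance"] == pytest.approx(2.0)

    def test_identical_cluster_means_score_zero(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 1.0, 2.0], "flat": np.ones(4)})
        imp = covariate_importance(table, self._schema(), np.array([1, 1, 2, 2]))
        assert imp.table.set_index("variable").loc["v", "importance"] == pytest.approx(0.0)

    def test_zero_variance_scores_zero_not_nan(self):
        table = pd.DataFrame({"v": np.arange(4.0), "flat": np.ones(4)})
        imp = covariate_importance(table, self._schema(), np.array([1, 1, 2, 2]))
        assert imp.table.set_index("variable").loc["flat", "importance"] == 0.0

    def test_selection_monotone_across_thresholds(self):
        table = pd.DataFrame(
            {"v": [0.0, 0.0, 0.26, 0.26], "flat": np.ones(4)}
        )
        imp = covariate_importance(table, self._schema(), np.array([1, 1, 2, 2]))
        sel = sensitivity_thresholds(imp)
        assert set(sel[0.30]) <= set(sel[0.25]) <= set(sel[0.20])

    def test_importance_just_above_quarter_selected_at_lower_thresholds_only(self):
        table = pd.DataFrame({"v": [0.0, 0.0, 1.0, 1.0], "flat": np.ones(4)})
        imp = covariate_importance(table, self._schema(), np.array([1, 1, 2, 2]))
        imp.table.loc[imp.table["variable"] == "v", "importance"] = 0.26
        assert "v" in imp.selected(0.20) and "v" in imp.selected(0.25)
        assert "v" not in imp.selected(0.30)

    def test_planted_modifiers_rank_top_three_on_oracle_effects(self, schema):
        hits = 0
        for seed in range(20):
            table, oracle = generate_cohort(recovery_config(n_total=1500, seed=seed), schema)
            z = jitter_standardize(oracle.true_ite, seed=seed)
            sol = beale_select_k(z, ward_cluster(z))
            imp = covariate_importance(table, schema, sol.labels)
            top3 = set(imp.table.head(3)["variable"])
            if "intention_improve_lifestyle" in top3 and "walking_activity" in top3:
                hits += 1
        assert hits >= 18


class TestClusterCate:
    def _cf(self, p1, p0):
        return CounterfactualPredictions(np.asarray(p1), np.asarray(p0), "binary")

    def test_single_cluster_equals_ate(self):
        rng = np.random.default_rng(0)
        p0 = rng.uniform(0.2, 0.8, 50)
        p1 = np.clip(p0 - 0.1, 0.01, 0.99)
        cf = self._cf(p1, p0)
        ite = ITEVector(cf.p1 - cf.p0)
        out = cluster_cate(ite, cf, np.ones(50, dtype=int), n_boot=50, seed=0)
        assert out[1].cate.point == pytest.approx(ite.ate, abs=1e-15)

    def test_sign_split_orders_cates(self):
        rng = np.random.default_rng(1)
        p0 = np.full(60, 0.5)
        p1 = np.concatenate([np.full(30, 0.3), np.full(30, 0.7)]) + rng.normal(0, 0.01, 60)
        cf = self._cf(np.clip(p1, 0.01, 0.99), p0)
        ite = ITEVector(cf.p1 - cf.p0)
        labels = np.where(ite.ite < 0, 1, 2)
        out = cluster_cate(ite, cf, labels, n_boot=50, seed=0)
        assert out[1].cate.point < 0 < out[2].cate.point

    def test_size_weighted_cate_mean_is_ate(self):
        rng = np.random.default_rng(2)
        p0 = rng.uniform(0.3, 0.7, 101)
        p1 = np.clip(p0 + rng.normal(0, 0.1, 101), 0.01, 0.99)
        cf = self._cf(p1, p0)
        ite = ITEVector(cf.p1 - cf.p0)
        labels = rng.integers(1, 4, 101)
        out = cluster_cate(ite, cf, labels, n_boot=10, seed=0)
        weighted = sum(e.n * e.cate.point for e in out.values()) / 101
        assert weighted == pytest.approx(ite.ate, abs=1e-12)

    def test_small_cluster_flagged_unstable(self):
        cf = self._cf(np.full(15, 0.4), np.full(15, 0.5))
        ite = ITEVector(cf.p1 - cf.p0)
        labels = np.array([1] * 12 + [2] * 3)
        out = cluster_cate(ite, cf, labels, n_boot=10, seed=0)
        assert not out[1].unstable
        assert out[2].unstable

    def test_continuous_outcome_has_no_ratio_summaries(self):
        cf = CounterfactualPredictions(
            np.array([-1.0] * 20), np.array([0.5] * 20), "continuous"
        )
        ite = ITEVector(cf.p1 - cf.p0)
        out = cluster_cate(ite, cf, np.ones(20, dtype=int), n_boot=10, seed=0)
        assert out[1].rr is None and out[1].e_value is None and out[1].nnt is None
        assert out[1].cate.scale == "mean difference"


class TestClusterProfile:
    def test_identical_clusters_have_identical_profiles(self):
        base = pd.DataFrame({"v": np.arange(10.0), "flat": np.ones(10)})
        table = pd.concat([base, base], ignore_index=True)
        labels = np.array([1] * 10 + [2] * 10)
        schema = CovariateSchema((Covariate("v", "continuous"), Covariate("flat", "continuous")))
        imp = covariate_importance(table, schema, labels)
        imp.table.loc[imp.table["variable"] == "v", "importance"] = 0.5
        prof = cluster_profile(table, schema, labels, imp, threshold=0.25)
        assert prof.loc[0, "v"] == prof.loc[1, "v"]

    def test_columns_ordered_by_importance_and_direction_recovered(self, schema):
        table, oracle = generate_cohort(recovery_config(n_total=1500, seed=3), schema)
        z = jitter_standardize(oracle.true_ite, seed=3)
        sol = beale_select_k(z, ward_cluster(z))
        imp = covariate_importance(table, schema, sol.labels)
        cf = CounterfactualPredictions(
            np.clip(0.5 + oracle.true_ite, 0.01, 0.99), np.full(1500, 0.5), "binary"
        )
        effects = cluster_cate(ITEVector(oracle.true_ite), cf, sol.labels, n_boot=10, seed=0)
        prof = cluster_profile(table, schema, sol.labels, imp, effects=effects)
        selected = imp.selected(0.25)
        assert list(prof.columns[-len(selected):]) == selected
        hb = prof[prof["role"] == "high-benefit"].iloc[0]
        lb = prof[prof["role"] == "low-benefit"].iloc[0]
        assert hb["intention_improve_lifestyle"] > lb["intention_improve_lifestyle"]

    def test_empty_selection_rejected(self):
        table = pd.DataFrame({"v": np.ones(4)})
        schema = CovariateSchema((Covariate("v", "continuous"),))
        labels = np.array([1, 1, 2, 2])
        imp = covariate_importance(table, schema, labels)
        with pytest.raises(ValueError, match="no covariate selected"):
            cluster_profile(table, schema, labels, imp, threshold=0.25)
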