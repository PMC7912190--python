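"""Mixed-data factor analysis, HCPC clustering and V-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from shedclimate import famd as F
from shedclimate import synthetic as S


class TestEncode:
    def test_quantitative_column_standardised_to_population_sd(self):
        enc = F.famd_encode(pd.DataFrame({"q": [1.0, 2.0, 3.0, 4.0]}))
        col = enc.X[:, 0]
        assert col.mean() == pytest.approx(0, abs=1e-12)
        assert col.std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_balanced_binary_indicators_are_mirror_images(self):
        enc = F.famd_encode(pd.DataFrame({"c": ["a", "a", "b", "b"]}))
        np.testing.assert_allclose(enc.X[:, 0], -enc.X[:, 1], atol=1e-12)

    def test_three_farm_toy_matches_hand_computed_matrix(self, toy_mixed_table):
        enc = F.famd_encode(toy_mixed_table)
        expected = np.array([
            # q standardised     (I_x - 2/3)/sqrt(2/3)  (I_y - 1/3)/sqrt(1/3)
            [-1.22474487,  0.40824829, -0.57735027],
            [0.0,          0.40824829, -0.57735027],
            [1.22474487,  -0.81649658,  1.15470054],
        ])
        np.testing.assert_allclose(enc.X, expected, atol=1e-7)

    def test_constant_quantitative_column_is_named_in_error(self):
        with pytest.raises(ValueError, match="RidgeHei"):
            F.famd_encode(pd.DataFrame({"RidgeHei": [3.0, 3.0, 3.0]}))

    def test_single_category_qualitative_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            F.famd_encode(pd.DataFrame({"q": [1.0, 2.0], "c": ["a", "a"]}))


class TestDecompose:
    def test_rank_one_data_explained_by_first_component(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        enc = F.famd_encode(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        dec = F.famd_decompose(enc)
        assert dec.proportions[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction_and_proportions_sum(self, default_farms):
        enc = F.famd_encode(default_farms,
                            quantitative=list(S.QUANTITATIVE_VARS),
                            qualitative=[c for c in S.QUALITATIVE_VARS
                                         if default_farms[c].nunique() > 1],
                            id_column="farm_id")
        dec = F.famd_decompose(enc)
        np.testing.assert_allclose(dec.scores @ dec.loadings.T, enc.X, atol=1e-8)
        assert dec.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_match_dense_eigensolver_oracle(self, default_farms):
        enc = F.famd_encode(default_farms,
                            quantitative=list(S.QUANTITATIVE_VARS),
                            qualitative=[c for c in S.QUALITATIVE_VARS
                                         if default_farms[c].nunique() > 1],
                            id_column="farm_id")
        dec = F.famd_decompose(enc)
        n = enc.X.shape[0]
        oracle = np.sort(np.linalg.eigvalsh(enc.X.T @ enc.X / n))[::-1]
        k = min(len(dec.eigenvalues), len(oracle))
        np.testing.assert_allclose(dec.eigenvalues[:k], oracle[:k], atol=1e-8)

    def test_duplicated_column_gets_identical_loadings(self):
        x = pd.DataFrame({"a": [1.0, 5.0, 2.0, 7.0], "b": [3.0, 0.0, 4.0, 1.0]})
        x["a2"] = x["a"]
        dec = F.famd_decompose(F.famd_encode(x))
        informative = dec.eigenvalues > 1e-10
        np.testing.assert_allclose(dec.loadings[0, informative],
                                   dec.loadings[2, informative], atol=1e-8)


class TestRetain:
    @pytest.mark.parametrize("props,thr,expected", [
        ([0.5, 0.3, 0.2], 0.70, 2),
        ([1.0], 1.0, 1),
        ([0.4, 0.2, 0.2, 0.1, 0.1], 0.70, 3),
    ])
    def test_examples(self, props, thr, expected):
        assert F.retain_components(props, thr) == expected

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            F.retain_components([0.6, 0.4], 1.5)

    def test_matches_cumulative_sum_oracle(self, default_farms):
        model = F.fit_housing_clusters(default_farms,
                                       drop_constant_qualitative=True)
        cum = np.cumsum(model.proportions)
        m = model.retained
        assert cum[m - 1] >= 0.70 - 1e-9
        assert m == 1 or cum[m - 2] < 0.70


class TestWardAndKMeans:
    def test_two_separated_clouds_suggest_two_clusters(self, rng):
        pts = np.vstack([rng.normal(0, 0.3, (20, 2)),
                         rng.normal(8, 0.3, (20, 2))])
        Z, k = F.hcluster_ward(pts, 2)
        assert k == 2

    def test_identical_points_are_degenerate(self):
        Z, k = F.hcluster_ward(np.ones((6, 2)), 2)
        assert k == 1

    def test_merge_heights_nondecreasing(self, rng):
        pts = rng.normal(size=(30, 3))
        Z, _ = F.hcluster_ward(pts, 3)
        assert np.all(np.diff(Z[:, 2]) >= -1e-10)

    def test_kmeans_fixed_point_on_optimal_partition(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, (10, 2)),
                         rng.normal(10, 0.2, (10, 2))])
        labels = np.repeat([1, 2], 10)
        out = F.kmeans_consolidate(pts, 2, init_labels=labels)
        np.testing.assert_array_equal(out, labels)

    def test_k_equals_n_gives_zero_inertia(self, rng):
        pts = rng.normal(size=(6, 2))
        out = F.kmeans_consolidate(pts, 6, init_labels=np.arange(1, 7))
        assert len(set(out)) == 6
        assert F._within_inertia(pts, out) == pytest.approx(0.0)

    def test_consolidation_never_increases_inertia(self, rng):
        pts = rng.normal(size=(40, 3)) + np.repeat(
            rng.normal(0, 3, (4, 3)), 10, axis=0)
        Z, _ = F.hcluster_ward(pts, 3)
        cut = fcluster(Z, 4, criterion="maxclust")
        before = F._within_inertia(pts, cut)
        after = F._within_inertia(pts, F.kmeans_consolidate(pts, 4, init_labels=cut))
        assert after <= before + 1e-9


class TestVTests:
    def test_zero_deviation_gives_v_zero_p_one(self):
        x = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        labels = np.array([1, 1, 2, 2, 3, 3])  # every cluster mean = 1.5
        t = F.vtest_quantitative(x, labels)
        np.testing.assert_allclose(t["v"], 0.0, atol=1e-12)
        np.testing.assert_allclose(t["p"], 1.0, atol=1e-12)

    def test_derived_formula_value(self):
        # N=32, n_k=4, group mean 2.88, overall mean 1.17, overall sd 1.09
        v = (2.88 - 1.17) / math.sqrt(((32 - 4) / 31) * 1.09**2 / 4)
        assert v == pytest.approx(3.3014, abs=1e-3)
        # implementation agrees on data constructed with those summaries
        cluster = np.array([2.88 - 1.0, 2.88 + 1.0, 2.88, 2.88])
        rest_mean = (32 * 1.17 - 4 * 2.88) / 28
        rest = np.full(28, rest_mean)
        x = np.concatenate([cluster, rest])
        x = (x - x.mean()) / x.std(ddof=0) * 1.09 + 1.17
        labels = np.array([1] * 4 + [2] * 28)
        got = F.vtest_quantitative(x, labels)
        row = got[got.cluster == 1].iloc[0]
        expected = (row["group_mean"] - 1.17) / math.sqrt((28 / 31) * 1.09**2 / 4)
        assert row["v"] == pytest.approx(expected, abs=1e-9)

    def test_singleton_cluster_is_finite(self, rng):
        x = rng.normal(size=10)
        labels = np.array([1] + [2] * 9)
        t = F.vtest_quantitative(x, labels)
        assert np.isfinite(t[t.cluster == 1]["v"].iloc[0])

    def test_constant_variable_not_applicable(self):
        t = F.vtest_quantitative(np.ones(8), np.repeat([1, 2], 4))
        assert t["v"].isna().all()

    def test_hypergeometric_tail_matches_enumeration_oracle(self):
        # cluster of 5, all sharing a category held by 7 of 32 farms
        N, K, nk, x = 32, 7, 5, 5
        oracle = sum(math.comb(K, i) * math.comb(N - K, nk - i)
                     for i in range(x, min(K, nk) + 1)) / math.comb(N, nk)
        cats = ["yes"] * 7 + ["no"] * 25
        labels = np.array([1] * 5 + [2] * 27)  # first five are all "yes"
        t = F.vtest_categorical(cats, labels, category="yes")
        row = t[(t.cluster == 1)].iloc[0]
        assert row["p"] == pytest.approx(min(1.0, 2 * oracle), rel=1e-9)
        assert row["v"] == pytest.approx(stats.norm.isf(oracle), rel=1e-9)
        assert row["v"] > 0

    def test_under_representation_has_negative_v(self):
        cats = ["yes"] * 28 + ["no"] * 4
        labels = np.array([1] * 4 + [2] * 28)
        t = F.vtest_categorical(cats[::-1], labels, category="yes")
        # cluster 1 holds the four "no" farms: "yes" absent though common
        assert t[t.cluster == 1]["v"].iloc[0] < 0

    def test_two_cluster_complement_symmetry(self, rng):
        cats = rng.choice(["a", "b"], size=20, p=[0.4, 0.6])
        labels = np.array([1] * 8 + [2] * 12)
        t = F.vtest_categorical(cats, labels, category="a")
        v1 = t[t.cluster == 1]["v"].iloc[0]
        v2 = t[t.cluster == 2]["v"].iloc[0]
        assert v1 == pytest.approx(-v2, abs=1e-6)


class TestFullPipeline:
    def test_archetype_recovery_with_default_fixture(self, archetype_farms):
        from sklearn.metrics import adjusted_rand_score
        model = F.fit_housing_clusters(
            archetype_farms.drop(columns="true_archetype"),
            drop_constant_qualitative=True)
        assert model.suggested_k == 7
        ari = adjusted_rand_score(archetype_farms["true_archetype"], model.labels)
        assert ari >= 0.9

    def test_every_farm_gets_exactly_one_label(self, default_farms):
        model = F.fit_housing_clusters(default_farms,
                                       drop_constant_qualitative=True)
        assert len(model.labels) == len(default_farms)
        assert model.assignments["cluster"].notna().all()

    def test_vtest_table_covers_all_variables(self, default_farms):
        model = F.fit_housing_clusters(default_farms,
                                       drop_constant_qualitative=True)
        assert set(S.QUANTITATIVE_VARS) <= set(model.vtests["variable"])
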