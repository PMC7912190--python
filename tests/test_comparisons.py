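"""Group-comparison battery: normality gate, ANOVA/Tukey, Kruskal/Dunn,
Fisher exact and the cluster two-way ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shedclimate import comparisons as C


class TestNormalityGate:
    def test_exact_normal_quantiles_pass(self):
        x = stats.norm.ppf((np.arange(50) + 0.5) / 50)
        decision, p = C.normality_gate(x, np.repeat("a", 50))
        assert decision == "normal"

    def test_lognormal_skew_detected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).lognormal(0, 1, 32)
            if C.normality_gate(x, np.repeat("a", 32))[0] == "non-normal":
                hits += 1
        assert hits >= 95

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            C.normality_gate([1.0, 2.0], ["a", "b"])

    def test_constant_data_is_non_normal(self):
        assert C.normality_gate(np.ones(10), np.repeat("a", 10))[0] == "non-normal"

    def test_gate_uses_group_residuals_not_raw_values(self, rng):
        # two far-apart normal groups: raw values are bimodal but residuals normal
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(50, 1, 40)])
        g = np.repeat(["a", "b"], 40)
        assert C.normality_gate(x, g)[0] == "normal"


class TestAnovaTukey:
    def test_two_groups_equal_equal_variance_t_test(self, rng):
        x = rng.normal(size=24)
        g = np.repeat(["a", "b"], 12)
        res = C.anova_tukey(x, g)
        _, p_t = stats.ttest_ind(x[:12], x[12:], equal_var=True)
        assert res.p_value == pytest.approx(p_t, rel=1e-9)

    def test_widely_separated_groups_get_distinct_letters(self, rng):
        means = [0, 10, 20, 30]
        x = np.concatenate([rng.normal(m, 1, 8) for m in means])
        g = np.repeat(list("abcd"), 8)
        res = C.anova_tukey(x, g)
        letters = list(res.letters.values())
        assert len(set(letters)) == 4

    def test_f_statistic_matches_sum_of_squares_oracle(self, rng):
        x = rng.normal(size=32) + np.repeat([0.0, 1.0, 2.0, 0.5], 8)
        g = np.repeat(list("abcd"), 8)
        res = C.anova_tukey(x, g)
        grand = x.mean()
        ss_between = sum(8 * (x[g == lev].mean() - grand) ** 2 for lev in "abcd")
        ss_within = sum(((x[g == lev] - x[g == lev].mean()) ** 2).sum()
                        for lev in "abcd")
        F = (ss_between / 3) / (ss_within / 28)
        assert res.statistic == pytest.approx(F, rel=1e-9)

    def test_small_groups_excluded_with_warning(self, rng):
        x = np.concatenate([rng.normal(size=10), [5.0]])
        g = np.array(["a"] * 5 + ["b"] * 5 + ["c"])
        with pytest.warns(UserWarning, match="excluding"):
            res = C.anova_tukey(x, g)
        assert "c" not in res.letters


class TestKruskalDunn:
    def test_two_groups_match_mann_whitney_normal_approximation(self, rng):
        x = np.round(rng.normal(size=20), 1)  # ties on purpose
        g = np.repeat(["a", "b"], 10)
        res = C.kruskal_dunn(x, g)
        mw = stats.mannwhitneyu(x[:10], x[10:], alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(mw.pvalue, rel=1e-6)

    def test_h_matches_rank_sum_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0])
        g = np.repeat(["a", "b", "c"], 3)
        res = C.kruskal_dunn(x, g)
        ranks = stats.rankdata(x)
        N = len(x)
        H = 12 / (N * (N + 1)) * sum(
            3 * ranks[g == lev].mean() ** 2 for lev in "abc") - 3 * (N + 1)
        _, counts = np.unique(x, return_counts=True)
        H /= 1 - (counts**3 - counts).sum() / (N**3 - N)
        assert res.statistic == pytest.approx(H, rel=1e-9)

    def test_identical_values_give_h_zero(self):
        res = C.kruskal_dunn(np.ones(12), np.repeat(["a", "b", "c"], 4))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_rarely_rejects(self):
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            x = np.random.default_rng(seed).normal(size=32)
            g = np.repeat(list("abcd"), 8)
            if C.kruskal_dunn(x, g).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.06


class TestFisher:
    def test_diagonal_table_exact_p(self):
        p, method = C.fisher_exact_rxc([[8, 0], [0, 8]])
        assert method == "enumeration"
        assert p == pytest.approx(2 / 12870, rel=1e-9)

    def test_identical_rows_give_p_one(self):
        p, _ = C.fisher_exact_rxc([[4, 4], [4, 4]])
        assert p == pytest.approx(1.0)

    def test_regional_housing_frequencies_highly_significant(self):
        # loose housing in 0, 8, 3, 8 of 8 farms per region
        counts = pd.DataFrame({"loose": [0, 8, 3, 8], "tie-up": [8, 0, 5, 0]},
                              index=["SL", "SH", "NL", "NH"])
        res = C.fisher_battery(counts)
        assert res.p_value < 0.001

    def test_enumeration_matches_scipy_on_small_2x2_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            M = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p_enum, method = C.fisher_exact_rxc(M)
            assert method == "enumeration"
            _, p_scipy = stats.fisher_exact(M)
            assert p_enum == pytest.approx(p_scipy, abs=1e-9), M

    def test_monte_carlo_fallback_close_to_enumeration(self):
        M = [[6, 2, 4], [1, 7, 3], [5, 2, 6]]
        p_enum, m1 = C.fisher_exact_rxc(M)
        p_mc, m2 = C.fisher_exact_rxc(M, max_tables=1, mc_draws=40_000, seed=3)
        assert m1 == "enumeration" and m2 == "monte-carlo"
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_empty_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            p, _ = C.fisher_exact_rxc([[3, 0, 2], [4, 0, 1]])
        assert 0 < p <= 1


class TestCompactLetters:
    def test_invariant_under_group_permutation(self):
        groups = ["g1", "g2", "g3", "g4"]
        means = [4.0, 3.0, 2.0, 1.0]
        sig = {frozenset(("g1", "g4")), frozenset(("g1", "g3"))}
        base = C.compact_letter_display(groups, means, sig)
        perm = [2, 0, 3, 1]
        shuffled = C.compact_letter_display([groups[i] for i in perm],
                                            [means[i] for i in perm], sig)
        assert base == shuffled

    def test_letters_reflect_significance(self):
        letters = C.compact_letter_display(
            ["a", "b"], [1.0, 0.0], {frozenset(("a", "b"))})
        assert set(letters["a"]).isdisjoint(set(letters["b"]))
        letters = C.compact_letter_display(["a", "b"], [1.0, 0.0], set())
        assert set(letters["a"]) & set(letters["b"])


class TestClusterTwoWayAnova:
    @staticmethod
    def _frame(rng, effect=0.0):
        n_per = 8
        rows = []
        for cl in (1, 2, 3):
            for _ in range(n_per):
                alt = rng.uniform(0, 1000)
                lat = rng.choice(["north", "south"])
                at = 30 - 0.004 * alt + effect * (cl == 2) + rng.normal(0, 1)
                rows.append({"cluster": cl, "altitude": alt,
                             "latitude_class": lat, "AT": at})
        return pd.DataFrame(rows)

    def test_injected_cluster_effect_detected(self):
        hits = 0
        for seed in range(60):
            df = self._frame(np.random.default_rng(seed), effect=5.0)
            if C.cluster_twoway_anova(df, "AT").p_value < 0.05:
                hits += 1
        assert hits >= 57  # 5-sd effect: essentially always detected

    def test_null_p_values_roughly_uniform(self):
        ps = [C.cluster_twoway_anova(
            self._frame(np.random.default_rng(seed)), "AT").p_value
            for seed in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_altitude_driven_response_shows_no_cluster_effect(self, rng):
        df = self._frame(rng)
        df["AT"] = 30 - 0.004 * df["altitude"]  # fully explained by altitude
        res = C.cluster_twoway_anova(df, "AT")
        assert res.p_value > 0.5 or np.isnan(res.p_value)

    def test_small_clusters_excluded(self, rng):
        df = self._frame(rng)
        df.loc[df.cluster == 2, "cluster"] = [2] * 2 + [3] * 6
        res = C.cluster_twoway_anova(df, "AT")
        assert set(res.group_summary["cluster"].astype(int)) == {1, 3}

    def test_requires_two_eligible_clusters(self, rng):
        df = self._frame(rng)
        df["cluster"] = 1
        with pytest.raises(ValueError, match="fewer than two"):
            C.cluster_twoway_anova(df, "AT")
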