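import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazeskill import cluster
from gazeskill.cluster import (
    GroupTestResult,
    assign_skill_levels,
    auto_group_test,
    compare_trainers,
    elbow_select,
    games_howell,
    kmeans_pp,
    oneway_anova,
    oneway_anova_with_tukey,
    tukey_hsd,
    welch_anova,
)
from gazeskill.metrics import FEATURE_COLUMNS

# Hand fixture; expected values frozen from pingouin / scipy oracles.
GROUP_A = [1.0, 2, 3, 4, 5]
GROUP_B = [2.0, 4, 6, 8, 10, 12]
GROUP_C = [5.0, 5, 6, 7, 9]


def blob_table(rng, centers, n_per, spread=0.05):
    rows = []
    for c, n in zip(centers, n_per):
        rows.append(rng.normal(0, spread, size=(n, len(FEATURE_COLUMNS))) + np.asarray(c))
    X = np.vstack(rows)
    return pd.DataFrame(X, columns=FEATURE_COLUMNS)


class TestKMeans:
    def test_blob_recovery(self):
        rng = np.random.default_rng(0)
        centers = [np.zeros(6), np.full(6, 3.0), np.r_[np.full(3, -3.0), np.full(3, 3.0)]]
        table = blob_table(rng, centers, [8, 8, 8], spread=0.1)
        truth = [0] * 8 + [1] * 8 + [2] * 8
        model = kmeans_pp(table, k=3, seed=0, n_init=10)
        assert cluster.adjusted_rand_index(model.assignments, truth) >= 0.9

    def test_k1_wcss_closed_form(self):
        rng = np.random.default_rng(1)
        table = blob_table(rng, [np.zeros(6)], [15], spread=1.0)
        model = kmeans_pp(table, k=1, seed=0, n_init=5)
        # z-scored columns each have sum of squares n (population sd)
        assert model.wcss_curve[1] == pytest.approx(15 * 6, rel=1e-9)

    def test_duplicate_rows_same_assignment(self):
        rng = np.random.default_rng(2)
        table = blob_table(rng, [np.zeros(6), np.full(6, 4.0)], [6, 6], spread=0.2)
        dup = pd.concat([table, table.iloc[[3]]], ignore_index=True)
        model = kmeans_pp(dup, k=2, seed=0, n_init=10)
        assert model.assignments[3] == model.assignments[len(dup) - 1]

    def test_k_exceeds_n_rejected(self):
        rng = np.random.default_rng(3)
        table = blob_table(rng, [np.zeros(6)], [4])
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_pp(table, k=5)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        table = blob_table(rng, [np.zeros(6), np.full(6, 4.0)], [6, 6])
        table["tool_speed"] = 7.0
        with pytest.warns(UserWarning, match="constant features"):
            model = kmeans_pp(table, k=2, seed=0, n_init=5)
        assert model.dropped_features == ["tool_speed"]
        assert "tool_speed" not in model.feature_names

    def test_wcss_nonincreasing(self):
        rng = np.random.default_rng(5)
        table = blob_table(rng, [np.zeros(6), np.full(6, 2.0)], [10, 10], spread=0.8)
        model = kmeans_pp(table, k=2, seed=0, n_init=10)
        vals = [model.wcss_curve[k] for k in sorted(model.wcss_curve)]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))


class TestElbow:
    def test_sharp_bend_at_three(self):
        curve = {1: 100.0, 2: 60.0, 3: 20.0, 4: 18.0, 5: 16.0}
        assert elbow_select(curve) == 3

    def test_linear_curve_flagged(self):
        curve = {1: 50.0, 2: 40.0, 3: 30.0, 4: 20.0, 5: 10.0}
        with pytest.warns(UserWarning, match="no clear elbow"):
            assert elbow_select(curve) == 2

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            elbow_select({1: 10.0, 2: 5.0})

    def test_tie_resolves_to_smaller_k(self):
        curve = {1: 100.0, 2: 50.0, 3: 25.0, 4: 12.5, 5: 12.5}
        # second differences: k=2: 25, k=3: 12.5, k=4: 12.5 -> max at 2
        assert elbow_select(curve) == 2


class TestWelchAnova:
    def test_matches_pingouin_frozen(self):
        res = welch_anova([GROUP_A, GROUP_B, GROUP_C])
        assert res.statistic == pytest.approx(6.081574344217493, abs=1e-9)
        assert res.df[0] == 2.0
        assert res.df[1] == pytest.approx(8.508012159540502, abs=1e-9)
        assert res.p == pytest.approx(0.022904681658975183, abs=1e-9)

    def test_brute_force_formula(self):
        # independent transcription of the Welch formulas
        gs = [np.asarray(g) for g in (GROUP_A, GROUP_B, GROUP_C)]
        k = 3
        n = np.array([g.size for g in gs])
        m = np.array([g.mean() for g in gs])
        v = np.array([g.var(ddof=1) for g in gs])
        w = n / v
        mw = (w * m).sum() / w.sum()
        num = ((w * (m - mw) ** 2).sum()) / (k - 1)
        h = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
        f_expected = num / (1 + 2 * (k - 2) / (k**2 - 1) * h)
        res = welch_anova(gs)
        assert res.statistic == pytest.approx(f_expected, abs=1e-10)

    def test_identical_constants_flagged(self):
        res = welch_anova([[3.0, 3.0, 3.0], [3.0, 3.0]])
        assert np.isnan(res.statistic) and "degenerate" in res.note

    def test_two_group_equals_squared_welch_t(self):
        g1 = [1.0, 2, 3, 4]
        g2 = [10.0, 12, 9, 14, 13]
        t, _ = stats.ttest_ind(g1, g2, equal_var=False)
        res = welch_anova([g1, g2])
        assert res.statistic == pytest.approx(t**2, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0], [2.0, 3.0]])


class TestGamesHowell:
    def test_matches_pingouin_frozen(self):
        table = {(c.group_a, c.group_b): c for c in games_howell([GROUP_A, GROUP_B, GROUP_C], names="abc")}
        assert table[("a", "b")].p == pytest.approx(0.109456, abs=1e-5)
        assert table[("a", "c")].p == pytest.approx(0.026237, abs=1e-5)
        assert table[("b", "c")].p == pytest.approx(0.934327, abs=1e-5)
        assert table[("a", "b")].difference == pytest.approx(-4.0)

    def test_ci_contains_difference(self):
        for c in games_howell([GROUP_A, GROUP_B, GROUP_C]):
            assert c.ci_low <= c.difference <= c.ci_high

    def test_identical_groups(self):
        g = [4.0, 5.0, 6.0]
        for c in games_howell([g, list(g)]):
            assert c.p == pytest.approx(1.0, abs=1e-9)
            assert c.ci_low <= 0.0 <= c.ci_high

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 1, 12)
        g2 = rng.normal(25, 1, 12)
        (c,) = games_howell([g1, g2])
        assert c.p < 1e-6 and not (c.ci_low <= 0.0 <= c.ci_high)


class TestAnovaTukey:
    def test_anova_frozen(self):
        res = oneway_anova([GROUP_A, GROUP_B, GROUP_C])
        assert res.statistic == pytest.approx(3.473615679824561, abs=1e-9)
        assert res.p == pytest.approx(0.061857836757359265, abs=1e-9)
        assert res.df == (2.0, 13.0)

    def test_tukey_matches_scipy_frozen(self):
        table = {(c.group_a, c.group_b): c for c in tukey_hsd([GROUP_A, GROUP_B, GROUP_C], names="abc")}
        assert table[("a", "b")].p == pytest.approx(0.06501853, abs=1e-6)
        assert table[("a", "c")].p == pytest.approx(0.14428919, abs=1e-6)
        assert table[("b", "c")].p == pytest.approx(0.92618653, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_tukey_matches_scipy_random(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-2, 2), 1.0, int(rng.integers(4, 10))) for _ in range(3)]
        sp = stats.tukey_hsd(*groups)
        ours = tukey_hsd(groups, names=["0", "1", "2"])
        for c in ours:
            i, j = int(c.group_a), int(c.group_b)
            assert c.p == pytest.approx(sp.pvalue[i, j], abs=1e-6)
            assert c.difference == pytest.approx(sp.statistic[i, j], abs=1e-9)

    def test_equal_means_p_near_one(self):
        g = [1.0, 2.0, 3.0]
        res = oneway_anova_with_tukey([g, list(g), list(g)])
        assert res.p == pytest.approx(1.0)
        assert all(c.p > 0.99 for c in res.pairwise)

    def test_auto_switches_on_levene(self):
        rng = np.random.default_rng(8)
        same_var = [rng.normal(0, 1, 15), rng.normal(1, 1, 15), rng.normal(2, 1, 15)]
        res = auto_group_test(same_var)
        assert res.name == "oneway_anova"
        uneq = [rng.normal(0, 0.1, 15), rng.normal(1, 5.0, 15), rng.normal(2, 10.0, 15)]
        res2 = auto_group_test(uneq)
        assert res2.name == "welch_anova"


class TestSkillLevels:
    # deterministic fixture: Games-Howell leaves exactly the (2,3) pair
    # non-significant (verified against the independent implementation)
    C1 = [100.0, 101.5, 98.6, 95.5, 97.7]
    C2 = [183.3, 216.9, 257.9, 199.2, 195.1, 230.7, 226.4, 218.4, 185.2, 214.1, 237.2, 172.0, 200.4, 154.2]
    C3 = [187.0, 162.1, 234.4, 188.0, 257.2]

    def _labels_times(self):
        labels = np.array([0] * 5 + [1] * 14 + [2] * 5)
        times = np.concatenate([self.C1, self.C2, self.C3])
        return labels, times

    def test_one_nonsignificant_pair_merges_to_two_levels(self):
        labels, times = self._labels_times()
        pvals = {(c.group_a, c.group_b): c.p for c in games_howell([self.C1, self.C2, self.C3], names="123")}
        assert pvals[("1", "2")] < 0.05 < pvals[("2", "3")] and pvals[("1", "3")] < 0.05
        sk = assign_skill_levels(labels, times)
        assert sk.level_order == ["HIGH", "MID_LOW"]
        assert sk.merge_map == {0: "HIGH", 1: "MID_LOW", 2: "MID_LOW"}
        assert set(sk.levels[:5]) == {"HIGH"} and set(sk.levels[5:]) == {"MID_LOW"}

    def test_all_pairs_significant_three_levels(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 8 + [1] * 8 + [2] * 8)
        times = np.concatenate(
            [rng.normal(100, 3, 8), rng.normal(200, 3, 8), rng.normal(300, 3, 8)]
        )
        sk = assign_skill_levels(labels, times)
        assert sk.level_order == ["HIGH", "MID", "LOW"]

    def test_all_pairs_nonsignificant_one_level(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 6 + [1] * 6 + [2] * 6)
        times = rng.normal(200, 50, 18)
        sk = assign_skill_levels(labels, times)
        assert len(sk.level_order) == 1

    def test_relabeling_invariance(self):
        labels, times = self._labels_times()
        sk1 = assign_skill_levels(labels, times)
        perm = {0: 7, 1: 2, 2: 5}
        sk2 = assign_skill_levels(np.array([perm[c] for c in labels]), times)
        assert np.array_equal(sk1.levels, sk2.levels)

    def test_single_cluster_warns(self):
        with pytest.warns(UserWarning, match="single cluster"):
            sk = assign_skill_levels(np.zeros(6, dtype=int), np.arange(6, dtype=float))
        assert sk.level_order == ["ALL"]


class TestCompareTrainers:
    @staticmethod
    def _table(paired_vals=None, indep=None):
        rows = []
        if paired_vals is not None:
            for pid, (a, b) in enumerate(paired_vals):
                rows.append({"participant_id": f"P{pid}", "trainer": "adult", "fr_objects": a})
                rows.append({"participant_id": f"P{pid}", "trainer": "pediatric", "fr_objects": b})
        if indep is not None:
            for pid, (tr, v) in enumerate(indep):
                rows.append({"participant_id": f"I{pid}", "trainer": tr, "fr_objects": v})
        return pd.DataFrame(rows)

    def test_identical_pairs(self):
        table = self._table(paired_vals=[(3.0, 3.0), (4.0, 4.0), (5.0, 5.0)])
        res = compare_trainers(table, metric_columns=["fr_objects"])["fr_objects"]
        assert res["paired"].statistic == 0.0 and res["paired"].p == 1.0

    def test_paired_t_closed_form(self):
        # differences (-1, -2, -2): t = -5, p = 0.0377495... (frozen scipy value)
        table = self._table(paired_vals=[(1.0, 2.0), (2.0, 4.0), (3.0, 5.0)])
        res = compare_trainers(table, metric_columns=["fr_objects"])["fr_objects"]
        assert res["paired"].statistic == pytest.approx(-5.0, abs=1e-9)
        assert res["paired"].p == pytest.approx(0.03774955135062371, abs=1e-9)

    def test_independent_welch(self):
        rng = np.random.default_rng(0)
        indep = [("adult", v) for v in rng.normal(5, 1, 8)] + [
            ("pediatric", v) for v in rng.normal(9, 2, 8)
        ]
        with pytest.warns(UserWarning, match="paired"):
            res = compare_trainers(self._table(indep=indep), metric_columns=["fr_objects"])
        assert res["fr_objects"]["independent"].p < 0.01
        assert res["fr_objects"]["paired"] is None

    def test_power_grows_with_effect(self):
        rng = np.random.default_rng(42)
        power = []
        for delta in (0.0, 0.8, 2.0):
            hits = 0
            for _ in range(200):
                a = rng.normal(0, 1, 10)
                b = a + rng.normal(delta, 1, 10)
                _, p = stats.ttest_rel(a, b)
                hits += p < 0.05
            power.append(hits / 200)
        assert power[0] < power[1] < power[2]
        assert power[0] < 0.15


def test_group_test_result_pairwise_frame():
    res = oneway_anova_with_tukey([GROUP_A, GROUP_B, GROUP_C], names="abc")
    df = res.pairwise_frame()
    assert list(df.columns) == ["group_a", "group_b", "difference", "ci_low", "ci_high", "p"]
    assert len(df) == 3
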