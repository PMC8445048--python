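"""Statistics layer: RM-ANOVA against independent GLM oracles, the
Greenhouse-Geisser epsilon, Holm-Sidak step-down against brute-force
enumeration, Welch's t, Tukey machinery and omega-squared."""

import numpy as np
import pytest
from scipy import stats as sps

from optoipsc import (ParameterError, bonferroni_adjust, gg_epsilon,
                      holm_sidak_adjust, multiple_welch_t,
                      omega_squared_within, pairwise_rm, rm_anova_one_way,
                      rm_anova_two_way, welch_t)


def glm_rm_f(x):
    """Independent oracle: one-way RM-ANOVA F via an OLS fit with subject and
    condition dummies (statsmodels), compared on the condition term."""
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    n, k = x.shape
    df = pd.DataFrame({"y": x.ravel(),
                       "subj": np.repeat(np.arange(n), k).astype(str),
                       "cond": np.tile(np.arange(k), n).astype(str)})
    fit = smf.ols("y ~ C(subj) + C(cond)", data=df).fit()
    tab = anova_lm(fit, typ=2)
    return float(tab.loc["C(cond)", "F"])


class TestRmAnovaOneWay:
    def test_identical_conditions_give_zero_f(self):
        x = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
        res = rm_anova_one_way(x, gg=False)
        assert res.F == 0.0

    def test_matches_independent_glm_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
        res = rm_anova_one_way(x, gg=False)
        assert res.F == pytest.approx(glm_rm_f(x), rel=1e-8)

    def test_gg_correction_never_lowers_p_when_f_above_one(self):
        # scaling both dfs by eps <= 1 inflates p for any F >= 1 (the regime
        # where the correction matters; below F = 1 nothing is significant)
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            x = rng.normal(size=(8, 4)) + rng.normal(size=(1, 4))
            res = rm_anova_one_way(x, gg=True)
            if res.F < 1.0:
                continue
            checked += 1
            assert res.p >= rm_anova_one_way(x, gg=False).p - 1e-12

    def test_too_small_table_rejected(self):
        with pytest.raises(ParameterError):
            rm_anova_one_way(np.ones((1, 3)))
        with pytest.raises(ParameterError):
            rm_anova_one_way(np.ones((4, 1)))


class TestGgEpsilon:
    def test_two_levels_always_one(self):
        rng = np.random.default_rng(0)
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_compound_symmetry_approaches_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 4)) + rng.normal(size=(200, 1))
        assert gg_epsilon(x) > 0.93

    def test_worst_case_hits_lower_bound(self):
        # all between-condition variance in a single contrast: eps -> 1/(k-1)
        rng = np.random.default_rng(2)
        z = rng.normal(size=(50, 1))
        x = np.hstack([z, -z, 1e-6 * rng.normal(size=(50, 2))])
        k = 4
        assert gg_epsilon(x) == pytest.approx(1.0 / (k - 1), rel=0.01)

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 4))
        assert gg_epsilon(x + 100.0) == pytest.approx(gg_epsilon(x), rel=1e-12)


class TestRmAnovaTwoWay:
    def test_matches_pingouin_mixed_anova(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 3))
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        mine = rm_anova_two_way(x, g, gg=False)
        df = pd.DataFrame({"y": x.ravel(),
                           "subj": np.repeat(np.arange(8), 3),
                           "time": np.tile(np.arange(3), 8),
                           "grp": np.repeat(g, 3)})
        ref = pg.mixed_anova(data=df, dv="y", within="time", subject="subj",
                             between="grp").set_index("Source")
        assert mine["between"].F == pytest.approx(ref.loc["grp", "F"], rel=1e-8)
        assert mine["within"].F == pytest.approx(ref.loc["time", "F"], rel=1e-8)
        assert mine["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)

    def test_constant_within_factor_zero_f(self):
        rng = np.random.default_rng(5)
        subj = rng.normal(size=(6, 1))
        x = np.tile(subj, (1, 3))
        g = np.array([0, 0, 0, 1, 1, 1])
        res = rm_anova_two_way(x, g, gg=False)
        assert res["within"].F == pytest.approx(0.0, abs=1e-18)

    def test_null_type_one_error_calibrated(self):
        # no-effect data: rejection rate ~ alpha over replicates
        rng = np.random.default_rng(6)
        alpha, n_rep = 0.05, 1000
        rejections = 0
        g = np.repeat([0, 1], 4)
        for _ in range(n_rep):
            x = rng.normal(size=(8, 3))
            res = rm_anova_two_way(x, g, gg=False)
            rejections += res["interaction"].p < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) < 2 * se

    def test_mismatched_groups_rejected(self):
        with pytest.raises(ParameterError):
            rm_anova_two_way(np.ones((6, 3)), np.array([0, 1, 0]))


def brute_force_holm_sidak(pvals):
    """Exhaustive step-down: at each step, the smallest remaining p is tested
    with the Sidak factor for the remaining family size."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for step, idx in enumerate(order):
        a = 1.0 - (1.0 - p[idx]) ** (m - step)
        running = max(running, min(a, 1.0))
        adj[idx] = running
    return adj


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak_adjust([0.04])[0] == pytest.approx(0.04)

    @pytest.mark.parametrize("pvals", [
        (0.01, 0.04, 0.03),
        (0.5, 0.001, 0.2, 0.9),
        (1.0, 1.0, 1.0),
        (0.049, 0.05, 0.051),
    ])
    def test_matches_brute_force_enumeration(self, pvals):
        assert np.allclose(holm_sidak_adjust(pvals), brute_force_holm_sidak(pvals))

    def test_adjusted_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=12)
        adj = holm_sidak_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            holm_sidak_adjust([0.5, 1.2])


class TestHolmSidakProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as hst

    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=10))
    @settings(derandomize=True, max_examples=60)
    def test_invariants_hold_for_any_family(self, pvals):
        adj = holm_sidak_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        assert np.allclose(adj, brute_force_holm_sidak(pvals))


class TestWelchT:
    def test_identical_samples_t_zero(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 14)
        mine = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_equal_variance_case_matches_pooled_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 0.8  # same variance, equal n: Welch == pooled exactly
        mine = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = [welch_t(rng.normal(size=8), rng.normal(size=8)).p
              for _ in range(2000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_zero_variance_flagged(self):
        r = welch_t([2.0, 2.0], [2.0, 2.0])
        assert r.degenerate


class TestOmegaSquared:
    def test_null_effect_zero(self):
        # MS_effect == MS_error built by construction -> clamped to 0
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 3))
        res = rm_anova_one_way(x, gg=False)
        res.ss["ms_cond"] = res.ss["ms_err"]
        assert omega_squared_within(res) == 0.0

    def test_hand_computed_toy_table(self):
        # 3 subjects x 3 conditions, sums of squares by hand:
        # total = 23, sum x^2 = 73 -> SS_total = 73 - 529/9 = 128/9
        # subject sums 6,10,7 -> SS_subj = 185/3 - 529/9 = 26/9
        # condition sums 4,7,12 -> SS_cond = 209/3 - 529/9 = 98/9
        # SS_err = 4/9; MS_cond = 49/9, MS_err = 1/9, MS_subj = 13/9
        # w2 = 2*(49/9 - 1/9) / (128/9 + 13/9) = 96/141
        x = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [1.0, 2.0, 4.0]])
        res = rm_anova_one_way(x, gg=False)
        assert res.ss["ss_total"] == pytest.approx(128.0 / 9.0, rel=1e-12)
        assert res.ss["ss_cond"] == pytest.approx(98.0 / 9.0, rel=1e-12)
        w2 = omega_squared_within(res)
        assert w2 == pytest.approx(96.0 / 141.0, rel=1e-12)
        assert 0.0 <= w2 <= 1.0


class TestPairwise:
    def test_tukey_orders_with_mean_separation(self):
        x = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [1.0, 2.0, 4.0],
                      [1.5, 2.5, 3.5]])
        cs = pairwise_rm(x, ["b", "d", "w"], method="tukey")
        p = dict(zip(cs.labels, cs.p_adj))
        assert p[("b", "w")] < p[("b", "d")]  # larger separation, smaller p

    def test_holm_sidak_adjusted_ge_raw(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(6, 4))
        cs = pairwise_rm(x, method="holm_sidak")
        assert np.all(cs.p_adj >= cs.p_raw - 1e-15)

    def test_bonferroni_dunn_is_plain_bonferroni(self):
        p = np.array([0.01, 0.2, 0.4])
        assert np.allclose(bonferroni_adjust(p), np.minimum(p * 3, 1.0))

    def test_multiple_welch_t_family(self):
        rng = np.random.default_rng(14)
        xs = [rng.normal(0, 1, 10) for _ in range(5)]
        ys = [rng.normal(0, 1, 10) for _ in range(5)]
        cs = multiple_welch_t(xs, ys)
        assert len(cs.p_adj) == 5 and np.all(cs.p_adj >= cs.p_raw - 1e-15)
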