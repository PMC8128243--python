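"""Second-level inference: t-tests, Holm, GG epsilon, ANOVAs, trends, power, BFs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy import stats as sps

from vaelab.stats import (
    cohens_f_from_F,
    gg_epsilon,
    holm_adjust,
    jzs_bf_ttest,
    mixed_anova,
    one_way_rm_anova,
    orthogonal_poly_coefficients,
    paired_t_power,
    polynomial_contrast,
    power_paired_t,
    rm_anova_two_way,
    ttest_effects,
)


class TestTTestEffects:
    def test_all_zero_differences(self):
        res = ttest_effects(np.zeros(10), kind="one_sample")
        assert res.t == 0 and res.d_z == 0 and res.p == 1.0

    def test_toy_pairs_hand_computation(self):
        """Pairs (1,2),(2,4),(3,3): t and g_av match hand-worked values."""
        x, y = np.array([2.0, 4, 3]), np.array([1.0, 2, 3])
        res = ttest_effects(x, y, kind="paired")
        # diffs (1,2,0): mean 1, sd 1 -> t = sqrt(3); sd(x)=1, sd(y)=1 -> d_av=1
        assert res.t == pytest.approx(math.sqrt(3))
        assert res.d_z == pytest.approx(1.0)
        J = math.exp(math.lgamma(2.0) - math.lgamma(1.5) - 0.5 * math.log(2.0))
        assert res.g_av == pytest.approx(1.0 * J)
        assert res.p == pytest.approx(2 * sps.t.sf(math.sqrt(3), 2))

    def test_scale_invariance_of_t(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        a = ttest_effects(x, y, kind="paired")
        b = ttest_effects(2 * x, 2 * y, kind="paired")
        assert a.t == pytest.approx(b.t)
        assert a.g_av == pytest.approx(b.g_av)

    def test_one_sample_matches_scipy(self, rng):
        x = rng.normal(0.5, 1, 20)
        res = ttest_effects(x, kind="one_sample")
        ref = sps.ttest_1samp(x, 0.0)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestHolm:
    def test_hand_step_down(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_and_degenerate(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])
        assert np.all(holm_adjust([1.0, 1.0]) == 1.0)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestGGEpsilon:
    def test_k2_forced_to_one(self, rng):
        y = rng.normal(size=(10, 2))
        assert gg_epsilon(np.cov(y, rowvar=False)) == pytest.approx(1.0)

    def test_compound_symmetry_gives_one(self):
        k = 4
        cov = 0.5 * np.ones((k, k)) + 0.5 * np.eye(k)
        assert gg_epsilon(cov) == pytest.approx(1.0)

    def test_rank_one_deviation_hits_lower_bound(self):
        """A single dominant contrast direction drives epsilon to 1/(k-1)."""
        k = 5
        u = np.zeros(k)
        u[0], u[1] = 1.0, -1.0  # pure contrast, survives double-centring
        cov = np.outer(u, u)
        assert gg_epsilon(cov) == pytest.approx(1.0 / (k - 1))

    def test_bounds_on_random_covariances(self, rng):
        for _ in range(20):
            a = rng.normal(size=(12, 4))
            eps = gg_epsilon(np.cov(a, rowvar=False))
            assert 1 / 3 - 1e-9 <= eps <= 1 + 1e-9


def _hand_two_way_ss(y):
    """Independent SS oracle via explicit mean loops."""
    n, a, b = y.shape
    g = y.mean()
    ss = dict.fromkeys(["s", "a", "b", "ab", "as", "bs", "abs", "total"], 0.0)
    for i in range(n):
        ss["s"] += a * b * (y[i].mean() - g) ** 2
    for j in range(a):
        ss["a"] += n * b * (y[:, j].mean() - g) ** 2
    for k in range(b):
        ss["b"] += n * a * (y[:, :, k].mean() - g) ** 2
    for j in range(a):
        for k in range(b):
            ss["ab"] += n * (y[:, j, k].mean() - y[:, j].mean()
                             - y[:, :, k].mean() + g) ** 2
    for i in range(n):
        for j in range(a):
            ss["as"] += b * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + g) ** 2
        for k in range(b):
            ss["bs"] += a * (y[i, :, k].mean() - y[i].mean()
                             - y[:, :, k].mean() + g) ** 2
    ss["total"] = ((y - g) ** 2).sum()
    ss["abs"] = ss["total"] - sum(ss[k] for k in ("s", "a", "b", "ab", "as", "bs"))
    return ss


class TestRmAnovaTwoWay:
    def test_toy_table_matches_hand_ss(self, rng):
        y = rng.normal(size=(3, 2, 2))
        tbl = rm_anova_two_way(y)
        ss = _hand_two_way_ss(y)
        by_effect = tbl.set_index("effect")
        assert by_effect.loc["A", "ss"] == pytest.approx(ss["a"])
        assert by_effect.loc["B", "ss"] == pytest.approx(ss["b"])
        assert by_effect.loc["A * B", "ss"] == pytest.approx(ss["ab"])
        assert by_effect.loc["A", "ss_error"] == pytest.approx(ss["as"])
        assert by_effect.loc["B", "ss_error"] == pytest.approx(ss["bs"])
        assert by_effect.loc["A * B", "ss_error"] == pytest.approx(ss["abs"])
        assert tbl.attrs["ss_subject"] == pytest.approx(ss["s"])

    def test_ss_terms_sum_to_total(self, rng):
        y = rng.normal(size=(8, 3, 4))
        tbl = rm_anova_two_way(y)
        total = (tbl["ss"].sum() + tbl["ss_error"].sum()
                 + tbl.attrs["ss_subject"])
        assert total == pytest.approx(tbl.attrs["ss_total"])

    def test_location_invariance(self, rng):
        y = rng.normal(size=(6, 3, 4))
        a = rm_anova_two_way(y)
        b = rm_anova_two_way(y + 100.0)
        assert np.allclose(a["F"], b["F"])

    def test_gg_p_at_least_uncorrected(self, rng):
        y = rng.normal(size=(10, 3, 4))
        tbl = rm_anova_two_way(y)
        assert (tbl["p_gg"] >= tbl["p_uncorrected"] - 1e-12).all()

    def test_matches_pingouin(self, rng):
        """F, dfs, uncorrected p, ng2 and main-effect GG eps vs pingouin."""
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(12, 3, 4)) + rng.normal(size=(12, 1, 1))
        rows = [(i, f"a{j}", f"b{k}", y[i, j, k])
                for i in range(12) for j in range(3) for k in range(4)]
        df = pd.DataFrame(rows, columns=["s", "A", "B", "v"])
        mine = rm_anova_two_way(df, dv="v", subject="s", within=("A", "B"))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(data=df, dv="v", within=["A", "B"], subject="s",
                              detailed=True, effsize="ng2")
        for i in range(3):
            assert mine["F"][i] == pytest.approx(ref["F"][i])
            assert mine["ss"][i] == pytest.approx(ref["SS"][i])
            assert mine["p_uncorrected"][i] == pytest.approx(ref["p_unc"][i])
            assert mine["generalized_eta_sq"][i] == pytest.approx(ref["ng2"][i])
        # pingouin's own two-way interaction eps is flagged unreliable upstream
        for i in range(2):
            assert mine["gg_epsilon"][i] == pytest.approx(ref["eps"][i])

    def test_null_type_one_error_calibrated(self):
        """Uncorrected F on iid (spherical) null data rejects at ~5%."""
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            y = rng.normal(size=(10, 3, 4))
            tbl = rm_anova_two_way(y)
            rejections += tbl["p_uncorrected"][2] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"s": [0, 0, 1], "A": ["x", "y", "x"],
                           "B": ["u", "u", "u"], "v": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_two_way(df, dv="v", subject="s", within=("A", "B"))


class TestMixedAnova:
    def test_between_dfs_match_design(self, rng):
        """Groups of 20 and 12 give between-effect dfs (1, 30)."""
        groups = [rng.normal(size=(20, 4)), rng.normal(size=(12, 4))]
        tbl = mixed_anova(groups)
        row = tbl.set_index("effect").loc["group"]
        assert (row["df_num"], row["df_den"]) == (1, 30)

    def test_identical_group_means_f_near_zero(self, rng):
        base = rng.normal(size=(10, 4))
        tbl = mixed_anova([base, base.copy()])
        assert tbl.set_index("effect").loc["group", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_toy_table_matches_hand_ss(self):
        y1 = np.array([[1.0, 2, 3], [2, 3, 4]])
        y2 = np.array([[2.0, 2, 2], [4, 5, 6], [0, 1, 2]])
        tbl = mixed_anova([y1, y2]).set_index("effect")
        allv = np.vstack([y1, y2])
        g = allv.mean()
        ss_total = ((allv - g) ** 2).sum()
        ss_bs = 3 * ((allv.mean(axis=1) - g) ** 2).sum()
        ss_g = 3 * (2 * (y1.mean() - g) ** 2 + 3 * (y2.mean() - g) ** 2)
        ss_w = 5 * ((allv.mean(axis=0) - g) ** 2).sum()
        ss_cells = (2 * ((y1.mean(axis=0) - g) ** 2).sum()
                    + 3 * ((y2.mean(axis=0) - g) ** 2).sum())
        ss_gw = ss_cells - ss_g - ss_w
        assert tbl.loc["group", "ss"] == pytest.approx(ss_g)
        assert tbl.loc["group", "ss_error"] == pytest.approx(ss_bs - ss_g)
        assert tbl.loc["W", "ss"] == pytest.approx(ss_w)
        assert tbl.loc["group * W", "ss"] == pytest.approx(ss_gw)
        assert tbl.loc["W", "ss_error"] == pytest.approx(
            ss_total - ss_bs - ss_w - ss_gw)

    def test_matches_pingouin_unbalanced(self, rng):
        pg = pytest.importorskip("pingouin")
        y1 = rng.normal(size=(9, 4))
        y2 = rng.normal(size=(6, 4)) + 0.4
        rows = []
        for gname, arr in (("g1", y1), ("g2", y2)):
            for i in range(arr.shape[0]):
                for k in range(4):
                    rows.append((f"{gname}_{i}", gname, f"w{k}", arr[i, k]))
        df = pd.DataFrame(rows, columns=["s", "g", "w", "v"])
        mine = mixed_anova(df, dv="v", subject="s", within="w", between="g")
        ref = pg.mixed_anova(data=df, dv="v", within="w", subject="s",
                             between="g", effsize="ng2")
        for i in range(3):
            assert mine["F"][i] == pytest.approx(ref["F"][i])
            assert mine["p_uncorrected"][i] == pytest.approx(ref["p_unc"][i])
            assert mine["generalized_eta_sq"][i] == pytest.approx(ref["ng2"][i])

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(101)
        reps, rej_g, rej_w = 2000, 0, 0
        for _ in range(reps):
            tbl = mixed_anova([rng.normal(size=(10, 4)),
                               rng.normal(size=(6, 4))])
            rej_g += tbl["p_uncorrected"][0] < 0.05
            rej_w += tbl["p_uncorrected"][1] < 0.05
        assert rej_g / reps == pytest.approx(0.05, abs=0.02)
        assert rej_w / reps == pytest.approx(0.05, abs=0.02)

    def test_subject_in_two_groups_rejected(self):
        df = pd.DataFrame({"s": ["a", "a"], "g": ["g1", "g2"],
                           "w": ["w1", "w1"], "v": [1.0, 2.0]})
        with pytest.raises(ValueError, match="exactly one group"):
            mixed_anova(df, dv="v", subject="s", within="w", between="g")


class TestPolynomialContrasts:
    def test_k4_linear_coefficients(self):
        assert np.allclose(orthogonal_poly_coefficients(4, 1), [-3, -1, 1, 3])
        assert np.allclose(orthogonal_poly_coefficients(4, 2), [1, -1, -1, 1])
        assert np.allclose(orthogonal_poly_coefficients(4, 3), [-1, 3, -3, 1])

    def test_contrast_df_n20_k4(self, rng):
        y = rng.normal(size=(20, 4))
        res = polynomial_contrast(y, "linear")
        assert res.df == 57

    def test_perfectly_linear_data_kills_higher_orders(self, rng):
        slopes = rng.uniform(0.5, 1.5, size=20)
        y = np.outer(slopes, np.arange(4.0)) + rng.normal(size=(20, 1))
        assert abs(polynomial_contrast(y, "quadratic").t) < 1e-8
        assert abs(polynomial_contrast(y, "cubic").t) < 1e-8
        assert polynomial_contrast(y, "linear").t > 10

    def test_positive_trend_detected(self, rng):
        y = rng.normal(size=(20, 4)) + np.linspace(0, 2, 4)
        res = polynomial_contrast(y, "linear")
        assert res.t > 0 and res.p < 0.01


class TestPower:
    def test_paper_sample_sizes(self):
        assert power_paired_t(0.94, alpha=0.05, target_power=0.80) == 11

    def test_published_table_value(self):
        assert power_paired_t(0.5, alpha=0.05, target_power=0.80) == 34

    def test_power_monotone_in_n(self):
        powers = [paired_t_power(n, 0.5) for n in range(5, 60, 5)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_paired_t(-0.5)
        with pytest.raises(ValueError):
            power_paired_t(0.5, alpha=1.5)


class TestCohensF:
    def test_pilot_interaction_value(self):
        assert cohens_f_from_F(3.32, 1.59, 6.36) == pytest.approx(0.91, abs=0.005)

    def test_zero_f(self):
        assert cohens_f_from_F(0.0, 2, 20) == 0.0

    @given(st.floats(min_value=0.01, max_value=50),
           st.floats(min_value=1, max_value=10),
           st.floats(min_value=5, max_value=100))
    def test_round_trip(self, F, dfn, dfd):
        f = cohens_f_from_F(F, dfn, dfd)
        assert f * f * dfd / dfn == pytest.approx(F, rel=1e-9)


def _jzs_oracle(t, n, r=math.sqrt(2) / 2):
    """Independent route: marginalize the noncentral-t likelihood over a
    Cauchy effect-size prior directly (no g-mixture)."""
    df = n - 1

    def num(delta):
        return sps.nct.pdf(t, df, delta * math.sqrt(n)) * sps.cauchy.pdf(delta, 0, r)

    val, _ = integrate.quad(num, -np.inf, np.inf, limit=300)
    return val / sps.t.pdf(t, df)


class TestJzsBayesFactor:
    def test_null_favoured_at_t_zero(self):
        assert jzs_bf_ttest(0.0, n=20) < 1.0

    @pytest.mark.parametrize("t,n", [(2.5, 20), (1.0, 12), (4.0, 30)])
    def test_matches_noncentral_t_quadrature_oracle(self, t, n):
        mine = jzs_bf_ttest(t, n=n)
        assert mine == pytest.approx(_jzs_oracle(t, n), rel=1e-3)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        assert jzs_bf_ttest(2.5, n=20) == pytest.approx(
            float(pg.bayesfactor_ttest(2.5, 20, paired=True)), rel=1e-3)

    def test_monotone_in_t(self):
        bfs = [jzs_bf_ttest(t, n=15) for t in np.linspace(0, 5, 11)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))

    def test_two_sample_form(self):
        bf = jzs_bf_ttest(2.0, n1=15, n2=10)
        assert bf > 0
        with pytest.raises(ValueError):
            jzs_bf_ttest(2.0)
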