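"""ANOVA decompositions, Tukey HSD, t-tests, 4PL curves, ELISA calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from zfsleep.stats import (
    StatsError,
    elisa_concentration,
    extra_ss_f,
    fit_fourpl,
    fit_standard_curve,
    fourpl,
    one_way_anova,
    students_t,
    tukey_hsd,
    two_way_anova,
)


class TestOneWay:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.f("group") == 0.0

    def test_hand_computed_decomposition(self):
        # groups [1,2] and [3,4]: grand mean 2.5, group means 1.5/3.5
        # SS_between = 2*(1)^2 + 2*(1)^2 = 4; SS_within = 0.5 + 0.5 = 1
        # F = (4/1) / (1/2) = 8
        res = one_way_anova([[1, 2], [3, 4]])
        row = res.table.iloc[0]
        assert row["ss"] == pytest.approx(4.0)
        assert res.table.iloc[1]["ss"] == pytest.approx(1.0)
        assert row["F"] == pytest.approx(8.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i * 0.3, 1, size=12) for i in range(4)]
        res = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.f("group") == pytest.approx(f_ref)
        assert res.p("group") == pytest.approx(p_ref)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError, match="empty"):
            one_way_anova([[1, 2], []])

    def test_invariances(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        f0 = one_way_anova(groups).f("group")
        shifted = [g + 17.0 for g in groups]
        scaled = [g * 3.5 for g in groups]
        assert one_way_anova(shifted).f("group") == pytest.approx(f0)
        assert one_way_anova(scaled).f("group") == pytest.approx(f0)


class TestTwoWay:
    @staticmethod
    def _layout(rng, effect_a=0.0, effect_b=0.0, inter=0.0, n=6):
        vals, fa, fb = [], [], []
        for a in (0, 1):
            for b in (0, 1):
                mu = a * effect_a + b * effect_b + a * b * inter
                vals.extend(rng.normal(mu, 1, n))
                fa.extend([f"a{a}"] * n)
                fb.extend([f"b{b}"] * n)
        return np.array(vals), np.array(fa), np.array(fb)

    def test_additive_cells_have_zero_interaction_ss(self):
        vals, fa, fb = [], [], []
        for a, ea in enumerate([0.0, 2.0]):
            for b, eb in enumerate([0.0, 3.0]):
                for _ in range(2):
                    vals.append(ea + eb)
                    fa.append(a)
                    fb.append(b)
        res = two_way_anova(vals, fa, fb)
        inter = res.table[res.table["effect"] == "A:B"].iloc[0]
        assert inter["ss"] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_factors_swaps_main_effects(self):
        rng = np.random.default_rng(7)
        vals, fa, fb = self._layout(rng, effect_a=1.0, effect_b=0.2)
        r1 = two_way_anova(vals, fa, fb)
        r2 = two_way_anova(vals, fb, fa)
        assert r1.f("A") == pytest.approx(r2.f("B"))
        assert r1.f("B") == pytest.approx(r2.f("A"))
        assert r1.f("A:B") == pytest.approx(r2.f("A:B"))

    def test_agrees_with_statsmodels(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(8)
        vals, fa, fb = self._layout(rng, effect_a=0.8, inter=0.5)
        res = two_way_anova(vals, fa, fb)
        df = pd.DataFrame({"y": vals, "a": fa, "b": fb})
        ref = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
        assert res.f("A") == pytest.approx(ref.loc["C(a)", "F"])
        assert res.f("B") == pytest.approx(ref.loc["C(b)", "F"])
        assert res.f("A:B") == pytest.approx(ref.loc["C(a):C(b)", "F"])

    def test_empty_cell_named_in_error(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        fa = ["x", "x", "y", "y", "x", "x"]
        fb = ["u", "u", "u", "u", "v", "v"]
        with pytest.raises(StatsError, match="'y'.*'v'"):
            two_way_anova(vals, fa, fb)

    def test_unbalanced_rejected(self):
        vals = list(range(9))
        fa = ["x"] * 5 + ["y"] * 4
        fb = (["u", "v"] * 5)[:9]
        with pytest.raises(StatsError):
            two_way_anova(vals, fa, fb)

    def test_total_ss_decomposes(self):
        rng = np.random.default_rng(9)
        vals, fa, fb = self._layout(rng, effect_a=1.0, effect_b=1.0, inter=1.0)
        res = two_way_anova(vals, fa, fb)
        total = ((vals - vals.mean()) ** 2).sum()
        assert res.table["ss"].sum() == pytest.approx(total)


class TestTukey:
    def test_equal_means_give_q_zero_p_one(self):
        res = tukey_hsd([[1, 2, 3], [2, 1, 3], [3, 2, 1]])
        assert (res.table["q"] == 0).all()
        np.testing.assert_allclose(res.table["p_adj"], 1.0)

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(i * 0.5, 1, 15) for i in range(3)]
        res = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for _, row in res.table.iterrows():
            i = int(row["group_i"][-1])
            j = int(row["group_j"][-1])
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_adjusted_p_at_least_pairwise_t(self):
        # against the unadjusted pooled-variance (LSD) pairwise t on the
        # same MS_within, the studentized-range adjustment can only inflate p
        rng = np.random.default_rng(11)
        for _ in range(1000):
            groups = [rng.normal(rng.normal(0, 0.5), 1, 8) for _ in range(3)]
            res = tukey_hsd(groups)
            for _, row in res.table.iterrows():
                i = int(row["group_i"][-1])
                j = int(row["group_j"][-1])
                se = np.sqrt(res.ms_within * (1 / len(groups[i]) + 1 / len(groups[j])))
                t = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
                p_t = 2 * sps.t.sf(t, res.df_within)
                assert row["p_adj"] >= p_t - 1e-9

    def test_monte_carlo_studentized_range_oracle(self):
        # P(Q > q0) for k=3, df=20 from simulation vs the distribution used
        rng = np.random.default_rng(12)
        n = 400_000
        z = rng.standard_normal((n, 3))
        s = np.sqrt(rng.chisquare(20, n) / 20)
        q = (z.max(axis=1) - z.min(axis=1)) / s
        q0 = 3.58  # near the 5% critical value
        mc = (q > q0).mean()
        exact = sps.studentized_range.sf(q0, 3, 20)
        assert abs(mc - exact) / exact < 0.02

    def test_p_monotone_in_mean_difference(self):
        base = np.array([-1.0, 0.0, 1.0])
        ps = []
        for delta in (0.5, 1.0, 2.0, 4.0):
            groups = [base, base + delta, base - delta]
            res = tukey_hsd(groups)
            ps.append(res.table["p_adj"].iloc[0])
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_needs_three_groups_and_variance(self):
        with pytest.raises(StatsError, match="three"):
            tukey_hsd([[1, 2], [3, 4]])
        with pytest.raises(StatsError, match="variance"):
            tukey_hsd([[1, 1], [2, 2], [3, 3]])


class TestStudentsT:
    def test_identical_groups(self):
        t, df, p = students_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert df == 4
        assert p == pytest.approx(1.0)

    def test_p_vanishes_as_jitter_shrinks(self):
        ps = []
        for eps in (1e-1, 1e-3, 1e-6):
            t, _, p = students_t([0, eps], [1, 1 + eps])
            ps.append(p)
        assert ps[0] > ps[1] > ps[2]
        assert ps[-1] < 1e-9

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            students_t([1, 1], [2, 2])


class TestFourPL:
    POWERS = np.round(np.logspace(0, np.log10(36.31), 14), 2)

    def test_noiseless_recovery(self):
        truth = (0.0, 0.9, np.log10(8.0), 2.0)
        y = fourpl(np.log10(self.POWERS), *truth)
        fit = fit_fourpl(np.log10(self.POWERS), y)
        assert fit.rss < 1e-10
        assert fit.bottom == pytest.approx(truth[0], abs=1e-5)
        assert fit.top == pytest.approx(truth[1], abs=1e-5)
        assert fit.logec50 == pytest.approx(truth[2], abs=1e-5)
        assert fit.hill == pytest.approx(truth[3], abs=1e-4)

    def test_midpoint_identity(self):
        y = fourpl(np.log10(self.POWERS), 0.1, 0.8, np.log10(5.0), 1.5)
        fit = fit_fourpl(np.log10(self.POWERS), y)
        mid = fit.predict(fit.ec50)
        assert mid == pytest.approx((fit.bottom + fit.top) / 2, rel=1e-6)

    def test_monotone_when_hill_positive(self):
        y = fourpl(np.log10(self.POWERS), 0.0, 0.8, np.log10(8.0), 1.8)
        fit = fit_fourpl(np.log10(self.POWERS), y + 0.01 * np.sin(self.POWERS))
        assert fit.hill > 0
        grid = fit.predict(np.logspace(-1, 2, 200))
        assert (np.diff(grid) >= -1e-12).all()

    def test_too_few_doses_rejected(self):
        with pytest.raises(StatsError, match="5 distinct"):
            fit_fourpl(np.log10([1, 2, 4, 8]), [0, 0.2, 0.5, 0.8])

    def test_decreasing_curve_normalization(self):
        # competitive-assay shape: absorbance falls with concentration
        y = fourpl(np.log10(self.POWERS), 2.0, 0.1, np.log10(4.0), 1.2)
        fit = fit_fourpl(np.log10(self.POWERS), y)
        assert fit.top >= fit.bottom
        assert fit.hill < 0
        np.testing.assert_allclose(fit.predict(self.POWERS), y, atol=1e-8)


class TestExtraSS:
    def test_formula_arithmetic(self):
        f, df_num, df_den, p = extra_ss_f(10.0, 12, 8.0, 10)
        assert f == pytest.approx(1.25)
        assert (df_num, df_den) == (2, 10)
        assert p == pytest.approx(sps.f.sf(1.25, 2, 10))

    def test_not_nested_rejected(self):
        with pytest.raises(StatsError, match="nested"):
            extra_ss_f(10.0, 10, 8.0, 10)
        with pytest.raises(StatsError, match="degrees"):
            extra_ss_f(10.0, 12, 8.0, 0)


class TestElisa:
    CONC = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0])

    def _curve(self):
        # competitive ELISA: absorbance decreases with histamine concentration
        truth = (0.15, 1.9, np.log10(3.0), -1.1)
        absb = np.empty_like(self.CONC)
        absb[0] = 2.0  # zero standard
        absb[1:] = fourpl(np.log10(self.CONC[1:]), *truth)
        return fit_standard_curve(self.CONC, absb), truth

    def test_inverse_identity_at_standards(self):
        curve, truth = self._curve()
        for c in self.CONC[1:]:
            a = float(curve.absorbance_at(c))
            est, flag = elisa_concentration(a, curve)
            assert flag == "ok"
            assert est == pytest.approx(c, rel=1e-6)

    def test_roundtrip_identity_to_1e9(self):
        curve, _ = self._curve()
        for c in np.geomspace(0.5, 32, 23):
            a = float(curve.absorbance_at(c))
            est, _ = elisa_concentration(a, curve)
            assert abs(est - c) < 1e-9 * max(1.0, c)

    def test_reading_below_zero_standard_clamps_to_exactly_zero(self):
        curve, _ = self._curve()
        # competitive assay: a sample with *more* absorbance than the 0
        # standard implies a negative concentration; it is rounded up to 0
        est, flag = elisa_concentration(curve.zero_absorbance + 0.05, curve)
        assert est == 0.0
        assert flag == "clamped_zero"

    def test_reading_above_top_standard_flagged(self):
        curve, _ = self._curve()
        a_top = float(curve.absorbance_at(32.0))
        est, flag = elisa_concentration(a_top - 0.01, curve)
        assert flag == "above_range"

    def test_standards_require_zero_point(self):
        with pytest.raises(StatsError, match="0-concentration"):
            fit_standard_curve(self.CONC[1:], np.linspace(2, 0.2, 7))


def test_all_p_values_in_unit_interval():
    rng = np.random.default_rng(13)
    for _ in range(50):
        groups = [rng.normal(rng.normal(0, 1), 1, 6) for _ in range(3)]
        assert 0.0 <= one_way_anova(groups).p("group") <= 1.0
        assert (tukey_hsd(groups).table["p_adj"].between(0, 1)).all()
        _, _, p = students_t(groups[0], groups[1])
        assert 0.0 <= p <= 1.0
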