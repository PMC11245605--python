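"""t tests, effect-size CIs, RM-ANOVA, post-hocs, ICC and Pearson CIs
checked against direct-formula oracles and independent implementations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srtkit.inferential import (
    cohens_d_ci,
    icc_absolute_agreement,
    one_sample_t,
    paired_t,
    pairwise_posthoc,
    pearson_r_ci,
    rm_anova_within,
)


def _long(values, factor="level", subject="subject"):
    n, k = values.shape
    rows = [
        {subject: f"s{i}", factor: f"l{j}", "value": values[i, j]}
        for i in range(n) for j in range(k)
    ]
    return pd.DataFrame(rows)


class TestTTests:
    def test_closed_form_small_sample(self):
        r = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert r.statistic == pytest.approx(2 * math.sqrt(3))
        assert r.df == 2

    def test_zero_variance_is_degenerate(self):
        r = one_sample_t([4.0, 4.0, 4.0], 4.0)
        assert r.degenerate
        assert r.p is None and r.statistic is None

    def test_against_textbook_formula_and_scipy(self, rng):
        x = rng.gamma(4, 5, 12)
        mu0 = 18.0
        r = one_sample_t(x, mu0)
        t_oracle = (x.mean() - mu0) / (x.std(ddof=1) / math.sqrt(len(x)))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), len(x) - 1)
        assert r.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert r.p == pytest.approx(p_oracle, abs=1e-10)
        ref = sps.ttest_1samp(x, mu0)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_paired_equals_one_sample_on_differences(self, rng):
        a, b = rng.normal(10, 2, 9), rng.normal(9, 2, 9)
        r = paired_t(a, b)
        o = one_sample_t(a - b, 0.0)
        assert r.statistic == pytest.approx(o.statistic)
        ref = sps.ttest_rel(a, b)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_paired_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        assert paired_t(a, b).statistic == pytest.approx(
            -paired_t(b, a).statistic)

    def test_identical_samples_give_degenerate_difference(self):
        r = paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert r.degenerate  # constant shift, zero diff-variance


class TestCohensDCI:
    def test_self_inversion(self):
        d, n, level = 0.9, 12, 0.95
        lo, hi = cohens_d_ci(d, n, level)
        t_obs = d * math.sqrt(n)
        # the noncentral-t at each bound places t_obs at the matching tail
        assert sps.nct.sf(t_obs, n - 1, lo * math.sqrt(n)) == pytest.approx(
            0.025, abs=1e-8)
        assert sps.nct.sf(t_obs, n - 1, hi * math.sqrt(n)) == pytest.approx(
            0.975, abs=1e-8)

    def test_null_effect_ci_roughly_symmetric(self):
        lo, hi = cohens_d_ci(0.0, 200)
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_width_shrinks_with_n(self):
        widths = [np.diff(cohens_d_ci(0.8, n))[0] for n in (5, 10, 20, 80)]
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))


class TestRmAnova:
    def test_no_level_effect_gives_zero_f(self, rng):
        base = rng.normal(10, 3, 6)
        y = np.tile(base[:, None], (1, 3))
        eff = rm_anova_within(_long(y), ["level"])["level"]
        assert eff.f == pytest.approx(0.0, abs=1e-18)

    def test_two_level_factor_forces_epsilon_one(self, rng):
        y = rng.normal(0, 1, (8, 2))
        eff = rm_anova_within(_long(y), ["level"])["level"]
        assert eff.epsilon == 1.0

    def test_hand_computed_sums_of_squares(self):
        # 4 subjects x 3 levels, decomposed by hand from the definitions
        y = np.array([[3.0, 4.0, 7.0],
                      [2.0, 4.0, 6.0],
                      [1.0, 3.0, 5.0],
                      [4.0, 6.0, 8.0]])
        grand = y.mean()
        ss_lvl = 4 * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_sub = 3 * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((y - grand) ** 2).sum() - ss_lvl - ss_sub
        eff = rm_anova_within(_long(y), ["level"])["level"]
        assert eff.ss_effect == pytest.approx(ss_lvl, abs=1e-8)
        assert eff.ss_error == pytest.approx(ss_err, abs=1e-8)
        f_oracle = (ss_lvl / 2) / (ss_err / 6)
        assert eff.f == pytest.approx(f_oracle, abs=1e-8)
        assert eff.eta_p2 == pytest.approx(ss_lvl / (ss_lvl + ss_err), abs=1e-10)

    def test_one_way_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(10, 2, (9, 4)) + np.arange(4) * 0.8
        long = _long(y)
        eff = rm_anova_within(long, ["level"])["level"]
        ref = pg.rm_anova(data=long, dv="value", within="level",
                          subject="subject", correction=True)
        p_unc = "p_unc" if "p_unc" in ref.columns else "p-unc"
        p_gg = "p_GG_corr" if "p_GG_corr" in ref.columns else "p-GG-corr"
        assert eff.f == pytest.approx(float(ref["F"][0]), abs=1e-8)
        assert eff.p == pytest.approx(float(ref[p_unc][0]), abs=1e-8)
        assert eff.epsilon == pytest.approx(float(ref["eps"][0]), abs=1e-8)
        assert eff.p_gg == pytest.approx(float(ref[p_gg][0]), abs=1e-8)

    def test_two_way_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n, a, b = 8, 3, 2
        y = rng.normal(10, 2, (n, a, b)) + np.arange(a)[None, :, None] * 1.5
        rows = [{"subject": i, "A": f"a{j}", "B": f"b{l}", "value": y[i, j, l]}
                for i in range(n) for j in range(a) for l in range(b)]
        long = pd.DataFrame(rows)
        eff = rm_anova_within(long, ["A", "B"])
        ref = pg.rm_anova(data=long, dv="value", within=["A", "B"],
                          subject="subject", correction=True, detailed=True)
        p_unc = "p_unc" if "p_unc" in ref.columns else "p-unc"
        for name, src in (("A", "A"), ("B", "B"), ("A*B", "A * B")):
            row = ref[ref["Source"] == src].iloc[0]
            assert eff[name].f == pytest.approx(float(row["F"]), abs=1e-8)
            assert eff[name].p == pytest.approx(float(row[p_unc]), abs=1e-8)
            assert eff[name].epsilon == pytest.approx(float(row["eps"]), abs=1e-6)

    def test_incomplete_subject_dropped_listwise(self, rng):
        y = rng.normal(0, 1, (5, 3))
        long = _long(y).drop(index=[1])  # subject s0 loses level l1
        with pytest.warns(UserWarning, match="listwise"):
            eff = rm_anova_within(long, ["level"])["level"]
        assert eff.n_subjects == 4


class TestPosthoc:
    def test_two_levels_methods_coincide(self, rng):
        y = rng.normal(0, 1, (10, 2)) + np.array([0.0, 0.7])
        long = _long(y)
        lsd = pairwise_posthoc(long, "level", "fisher_lsd")
        bon = pairwise_posthoc(long, "level", "bonferroni")
        assert len(lsd) == len(bon) == 1
        assert lsd[0].p == pytest.approx(bon[0].p)

    def test_bonferroni_is_m_times_lsd_capped(self, rng):
        y = rng.normal(0, 1, (8, 3)) + np.arange(3) * 0.5
        long = _long(y)
        lsd = pairwise_posthoc(long, "level", "fisher_lsd")
        bon = pairwise_posthoc(long, "level", "bonferroni")
        for l, b in zip(lsd, bon):
            assert b.p == pytest.approx(min(1.0, l.p * 3), abs=1e-12)
            assert b.p >= l.p

    def test_unknown_method_rejected(self, rng):
        y = rng.normal(0, 1, (4, 2))
        with pytest.raises(ValueError):
            pairwise_posthoc(_long(y), "level", "tukey")


class TestIcc:
    def test_identical_raters_give_unity(self):
        col = np.array([1.0, 5.0, 3.0, 8.0, 2.0, 7.0])
        res = icc_absolute_agreement(np.column_stack([col] * 3))
        assert res.icc == pytest.approx(1.0)

    def test_pure_noise_raters_give_near_zero(self, rng):
        x = rng.normal(0, 1, (500, 3))  # no item variance share
        res = icc_absolute_agreement(x)
        assert abs(res.icc) < 0.15

    def test_hand_computed_mean_squares(self):
        x = np.array([[9.0, 2.0, 5.0],
                      [6.0, 1.0, 3.0],
                      [8.0, 4.0, 6.0],
                      [7.0, 1.0, 2.0],
                      [10.0, 5.0, 6.0],
                      [6.0, 2.0, 4.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2
               ).sum() / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (msc - mse) / n)
        res = icc_absolute_agreement(x)
        assert res.icc == pytest.approx(oracle, abs=1e-8)
        assert res.f == pytest.approx(msr / mse, abs=1e-8)

    def test_matches_pingouin_icc2k(self, rng):
        pg = pytest.importorskip("pingouin")
        truth = rng.gamma(4, 5, 30)
        x = truth[:, None] + rng.normal(0, 2, (30, 3)) + np.array([0.0, 1.0, -0.5])
        res = icc_absolute_agreement(x)
        df = pd.DataFrame(x, columns=list("abc")).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        ref = pg.intraclass_corr(df, targets="index", raters="rater",
                                 ratings="score")
        row = ref[ref["Type"] == "ICC2k"].iloc[0] if (ref["Type"] == "ICC2k").any() \
            else ref[ref["Type"] == "ICC(A,k)"].iloc[0]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-8)
        assert res.f == pytest.approx(float(row["F"]), abs=1e-8)

    def test_growing_rater_offsets_depress_agreement(self, rng):
        truth = rng.gamma(4, 5, 40)
        base = truth[:, None] + rng.normal(0, 1, (40, 3))
        iccs = []
        for off in (0.0, 3.0, 8.0):
            x = base + np.array([0.0, off, -off])
            iccs.append(icc_absolute_agreement(x).icc)
        assert iccs[0] > iccs[1] > iccs[2]

    def test_incomplete_matrix_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_absolute_agreement(x)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, ci, _ = pearson_r_ci(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson_r_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_against_direct_formula(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r, ci, res = pearson_r_ci(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)
        z = math.atanh(r)
        se = 1 / math.sqrt(27)
        assert ci[0] == pytest.approx(math.tanh(z - 1.959963984540054 * se), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
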