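"""Dual-criterion tests, repeated-measures ANOVA and confidence intervals.

The ANOVA implementation is cross-checked against two independent oracles:
pingouin (one- and two-way, including the Greenhouse-Geisser correction and
partial eta squared) and statsmodels' AnovaRM (three-way F and df).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import facemorph as fm
from facemorph.stats import dual_paired_test, letter_display, mean_ci, rm_anova


def exact_signed_rank_p(d):
    """Two-sided exact Wilcoxon p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    n = d.size
    stats = np.array([ranks[np.array(signs, bool)].sum()
                      for signs in itertools.product((0, 1), repeat=n)])
    lo = np.mean(stats <= t_obs)
    hi = np.mean(stats >= t_obs)
    return min(1.0, 2.0 * min(lo, hi))


def hand_t_p(d):
    """Paired-t p from the closed-form statistic and the t distribution."""
    d = np.asarray(d, float)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    return 2.0 * sps.t.sf(abs(t), d.size - 1)


class TestDualPairedTest:
    def test_identical_samples_not_significant(self):
        a = np.arange(10.0)
        res = dual_paired_test(a, a.copy())
        assert not res.significant and np.isnan(res.p_w)

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError):
            dual_paired_test([1, 2, 3], [2, 3, 4])

    def test_pvalues_match_exact_oracles(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 1.0, 10)
        b = a - rng.normal(0.6, 0.8, 10)
        res = dual_paired_test(a, b)
        assert res.p_t == pytest.approx(hand_t_p(a - b), abs=1e-6)
        assert res.p_w == pytest.approx(exact_signed_rank_p(a - b), abs=1e-6)

    def test_decision_is_a_conjunction(self):
        # a strong mean shift carried by two extreme pairs: the t-test
        # fires but the rank test does not
        a = np.array([0.1, -0.2, 0.05, -0.1, 0.15, -0.05, 8.0, 9.0])
        b = np.zeros(8)
        res = dual_paired_test(a, b, alpha=0.05)
        assert (res.p_t < 0.05) != (res.p_w < 0.05) or not res.significant
        assert res.significant == (res.p_t < 0.05 and res.p_w < 0.05)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        for alpha in (0.001, 0.01, 0.05, 0.1):
            r_small = dual_paired_test(a, b, alpha=alpha)
            r_large = dual_paired_test(a, b, alpha=alpha * 2)
            assert (not r_small.significant) or r_large.significant

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.3, 1.0, 30)
        res = dual_paired_test(a, np.zeros(30))
        ref = sps.wilcoxon(a, method="approx", correction=True).pvalue
        assert res.p_w == pytest.approx(float(ref))


class TestMeanCI:
    def test_constant_sample_zero_width(self):
        m, lo, hi = mean_ci(np.full(8, 3.3))
        assert m == lo == hi == pytest.approx(3.3)

    def test_closed_form_small_sample(self):
        m, lo, hi = mean_ci([1.0, 2.0, 3.0, 4.0])
        se = np.std([1, 2, 3, 4], ddof=1) / 2.0
        half = sps.t.ppf(0.975, 3) * se
        assert m == pytest.approx(2.5)
        assert hi - m == pytest.approx(half)
        assert m - lo == pytest.approx(half)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(1.0, 2.0, 15)
            _, lo, hi = mean_ci(x)
            hits += lo <= 1.0 <= hi
        assert 0.93 <= hits / n_rep <= 0.97


def _long(values, factors, dv="y"):
    """values: subjects x cells array; factors: list of (name, levels)."""
    rows = []
    cells = list(itertools.product(*[lv for _, lv in factors]))
    for s, row in enumerate(values):
        for cell, v in zip(cells, row):
            rows.append({"subject": s, dv: v,
                         **{name: lev for (name, _), lev in zip(factors, cell)}})
    return pd.DataFrame(rows)


class TestRMAnova:
    def test_no_effect_gives_zero_f(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 12)
        data = _long(np.tile(base[:, None], (1, 3)), [("cond", list("abc"))])
        row = rm_anova(data, "y", "cond", "subject").iloc[0]
        assert row["F"] == 0.0

    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (14, 2))
        vals[:, 1] += 0.5
        data = _long(vals, [("cond", ["a", "b"])])
        row = rm_anova(data, "y", "cond", "subject").iloc[0]
        t = sps.ttest_rel(vals[:, 0], vals[:, 1])
        assert row["F"] == pytest.approx(t.statistic ** 2, abs=1e-6)
        assert row["p"] == pytest.approx(t.pvalue, abs=1e-9)

    def test_one_way_matches_pingouin_with_gg(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (10, 4)) + rng.normal(0, 0.5, 4)
        data = _long(vals, [("cond", list("abcd"))], dv="score")
        mine = rm_anova(data, "score", "cond", "subject").iloc[0]
        ref = pg.rm_anova(data=data, dv="score", within="cond",
                          subject="subject", correction=True,
                          effsize="np2").iloc[0]
        assert mine["F"] == pytest.approx(float(ref["F"]), rel=1e-9)
        assert mine["p"] == pytest.approx(float(ref["p_unc"]), rel=1e-9)
        assert mine["np2"] == pytest.approx(float(ref["np2"]), rel=1e-6)
        assert mine["gg_eps"] == pytest.approx(float(ref["eps"]), rel=1e-6)
        assert mine["p_gg"] == pytest.approx(float(ref["p_GG_corr"]), rel=1e-6)

    def test_two_way_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (12, 6))
        vals[:, :3] += 0.8
        data = _long(vals, [("a", ["x", "y"]), ("b", ["p", "q", "r"])],
                     dv="score")
        mine = rm_anova(data, "score", ["a", "b"], "subject").set_index("effect")
        ref = pg.rm_anova(data=data, dv="score", within=["a", "b"],
                          subject="subject", effsize="np2").set_index("Source")
        pairs = {"a": "a", "b": "b", "a:b": "a * b"}
        for eff, src in pairs.items():
            assert mine.loc[eff, "F"] == pytest.approx(float(ref.loc[src, "F"]),
                                                       rel=1e-6)
            assert mine.loc[eff, "p"] == pytest.approx(float(ref.loc[src, "p_unc"]),
                                                       rel=1e-6, abs=1e-12)

    def test_three_way_matches_anovarm(self):
        sm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (9, 2 * 2 * 4))
        data = _long(vals, [("a", ["x", "y"]), ("b", ["p", "q"]),
                            ("c", list("1234"))])
        mine = rm_anova(data, "y", ["a", "b", "c"], "subject").set_index("effect")
        ref = sm.AnovaRM(data, "y", "subject", within=["a", "b", "c"]).fit() \
            .anova_table
        pairs = {"a": "a", "b": "b", "c": "c", "a:b": "a:b", "a:c": "a:c",
                 "b:c": "b:c", "a:b:c": "a:b:c"}
        for eff, src in pairs.items():
            assert mine.loc[eff, "F"] == pytest.approx(
                float(ref.loc[src, "F Value"]), rel=1e-6)
            assert mine.loc[eff, "df1"] == ref.loc[src, "Num DF"]
            assert mine.loc[eff, "df2"] == ref.loc[src, "Den DF"]

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(8)
        data = _long(rng.normal(0, 1, (6, 3)), [("cond", list("abc"))])
        with pytest.raises(ValueError):
            rm_anova(data.iloc[:-1], "y", "cond", "subject")

    def test_eta_squared_degenerate_guards(self):
        # zero between-level variance -> 0; zero error variance -> 1
        flat = _long(np.tile(np.arange(8.0)[:, None], (1, 3)),
                     [("cond", list("abc"))])
        assert rm_anova(flat, "y", "cond", "subject").iloc[0]["np2"] == 0.0
        pure = _long(np.tile([1.0, 2.0, 4.0], (8, 1)), [("cond", list("abc"))])
        assert rm_anova(pure, "y", "cond", "subject").iloc[0]["np2"] == 1.0

    def test_corrected_df_never_exceed_uncorrected(self):
        rng = np.random.default_rng(9)
        data = _long(rng.normal(0, 1, (10, 5)), [("cond", list("abcde"))])
        row = rm_anova(data, "y", "cond", "subject").iloc[0]
        assert row["df1_gg"] <= row["df1"] and row["df2_gg"] <= row["df2"]
        assert row["gg_eps"] >= 1.0 / (row["df1"])


class TestLetterDisplay:
    def test_groups_that_differ_get_distinct_letters(self):
        rng = np.random.default_rng(10)
        base = rng.normal(5.0, 0.1, 20)
        frame = pd.DataFrame({
            "subject": np.tile(np.arange(20), 3),
            "cond": np.repeat(["A", "B", "C"], 20),
            "v": np.concatenate([base, base + rng.normal(0, 0.05, 20),
                                 base + 2.0]),
        })
        letters = letter_display(frame, "cond", "v", "subject")
        assert letters["A"] == letters["B"]
        assert set(letters["C"]) & set(letters["A"]) == set()
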