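import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import exact_correlation_pair
from swaynet.group_stats import (SampleSummary, bonferroni, chi_square_2x2,
                                 fdr_bh, levene_test, mixed_anova_2x2,
                                 partial_eta_squared, pearson_corr_test,
                                 pooled_t_test, simple_effects, welch_t_test)

#: published demographic summaries of the two cohorts (mean, sd, n) and the
#: statistics they imply — frozen worked examples
DEMOGRAPHICS = {
    "age": ((67.26, 2.77, 34), (66.82, 3.30, 34), 0.595),
    "height": ((163.00, 7.69, 34), (160.03, 6.25, 34), 1.748),
    "weight": ((68.05, 9.25, 34), (64.75, 7.59, 34), 1.608),
}


class TestPooledT:
    @pytest.mark.parametrize("name", sorted(DEMOGRAPHICS))
    def test_reproduces_published_statistics(self, name):
        (a, b, expected) = DEMOGRAPHICS[name]
        t, df, p = pooled_t_test(SampleSummary(*a), SampleSummary(*b))
        assert round(t, 3) == expected
        assert df == 66

    def test_identical_summaries(self):
        s = SampleSummary(5.0, 1.0, 10)
        t, df, p = pooled_t_test(s, s)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetric_under_swap(self):
        a, b = SampleSummary(5.0, 1.0, 12), SampleSummary(6.0, 2.0, 15)
        assert pooled_t_test(a, b)[0] == pytest.approx(-pooled_t_test(b, a)[0])

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pooled_t_test(SampleSummary(1.0, 0.0, 5), SampleSummary(2.0, 0.0, 5))

    def test_welch_close_to_pooled_for_equal_n_and_var(self):
        a, b = SampleSummary(5.0, 2.0, 20), SampleSummary(6.0, 2.0, 20)
        assert welch_t_test(a, b)[0] == pytest.approx(pooled_t_test(a, b)[0])


class TestChiSquare:
    def test_reproduces_published_sex_statistic(self):
        chi2, df, p = chi_square_2x2([[12, 22], [6, 28]])
        assert chi2 == pytest.approx(2.720, abs=5e-4)
        assert df == 1

    def test_proportional_rows_zero(self):
        assert chi_square_2x2([[10, 20], [5, 10]])[0] == pytest.approx(0.0)

    def test_matches_expected_count_oracle(self, rng):
        for _ in range(20):
            tbl = rng.integers(1, 40, size=(2, 2)).astype(float)
            exp = np.outer(tbl.sum(1), tbl.sum(0)) / tbl.sum()
            oracle = ((tbl - exp) ** 2 / exp).sum()
            assert chi_square_2x2(tbl)[0] == pytest.approx(oracle, abs=1e-10)

    def test_row_column_swap_invariance(self):
        base = chi_square_2x2([[12, 22], [6, 28]])[0]
        assert chi_square_2x2([[6, 28], [12, 22]])[0] == pytest.approx(base)
        assert chi_square_2x2([[22, 12], [28, 6]])[0] == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestLevene:
    def test_identical_groups_zero(self):
        w, p = levene_test([1, 2, 3], [1, 2, 3])
        assert w == pytest.approx(0.0)

    def test_matches_anova_on_absolute_deviations(self):
        g1, g2 = [1.0, 2.0, 3.0], [0.0, 4.0, 8.0]
        w, p = levene_test(g1, g2)
        d1 = np.abs(np.array(g1) - np.mean(g1))
        d2 = np.abs(np.array(g2) - np.mean(g2))
        f_oracle, p_oracle = sps.f_oneway(d1, d2)
        assert w == pytest.approx(f_oracle)
        assert p == pytest.approx(p_oracle)

    def test_location_shift_invariance(self, rng):
        g = rng.standard_normal(30)
        w, _ = levene_test(g, g + 5.0)
        assert w == pytest.approx(0.0, abs=1e-10)


def long_frame(rng, n=10, shift=None):
    rows = []
    for gi, g in enumerate(("MCI", "CN")):
        for i in range(n):
            pid = f"{g}{i}"
            base = rng.standard_normal()
            for c in ("open", "closed"):
                val = base + rng.standard_normal()
                if shift:
                    val += shift.get((g, c), 0.0)
                rows.append({"participant": pid, "group": g,
                             "condition": c, "value": val})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_no_condition_difference_zero_f(self, rng):
        rows = []
        for g in ("MCI", "CN"):
            for i in range(6):
                v = rng.standard_normal()
                for c in ("open", "closed"):
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "condition": c, "value": v})
        tab = mixed_anova_2x2(pd.DataFrame(rows))
        assert tab.loc["condition", "F"] == pytest.approx(0.0, abs=1e-20)
        assert tab.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            df = long_frame(rng)
            mine = mixed_anova_2x2(df)
            ref = pingouin.mixed_anova(data=df, dv="value", within="condition",
                                       between="group", subject="participant")
            ref = ref.set_index(ref["Source"].str.lower())
            for effect, key in (("condition", "condition"),
                                ("group", "group"),
                                ("interaction", "interaction")):
                assert mine.loc[effect, "F"] == pytest.approx(
                    ref.loc[key, "F"], abs=1e-8)
                assert mine.loc[effect, "eta_p_sq"] == pytest.approx(
                    ref.loc[key, "np2"], abs=1e-8)

    def test_eta_identity(self, rng):
        tab = mixed_anova_2x2(long_frame(rng))
        for _, row in tab.iterrows():
            assert row["eta_p_sq"] == pytest.approx(
                partial_eta_squared(row["F"], 1, row["df2"]), abs=1e-12)

    def test_missing_condition_names_participant(self, rng):
        df = long_frame(rng)
        df = df[~((df["participant"] == "MCI3") & (df["condition"] == "open"))]
        with pytest.raises(ValueError, match="MCI3"):
            mixed_anova_2x2(df)

    def test_published_eta_examples(self):
        # F(1,66) pairs printed with their effect sizes
        assert round(partial_eta_squared(30.294, 1, 66), 3) == 0.315
        assert round(partial_eta_squared(70.120, 1, 66), 3) == 0.515


class TestSimpleEffects:
    def test_identical_groups_adjusted_p_one(self, rng):
        rows = []
        vals = rng.standard_normal(6)
        for g in ("MCI", "CN"):
            for i in range(6):
                for c, v in (("open", vals[i]), ("closed", vals[i] + 1)):
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "condition": c, "value": v})
        se = simple_effects(pd.DataFrame(rows))
        between = se[se["family"] == "between"]
        assert np.allclose(between["p_adj"], 1.0)

    def test_within_shift_detected_between_not(self, rng):
        shift = {("MCI", "closed"): 3.0, ("CN", "closed"): 3.0}
        se = simple_effects(long_frame(rng, n=15, shift=shift))
        within = se[se["family"] == "within"]
        between = se[se["family"] == "between"]
        assert (within["p_adj"] < 0.05).all()
        assert (between["p_adj"] > 0.05).all()

    def test_matches_subset_t_oracle(self, rng):
        df = long_frame(rng)
        se = simple_effects(df).set_index("contrast")
        wide = df.pivot_table(index=["participant", "group"],
                              columns="condition", values="value").reset_index()
        mci = wide[wide["group"] == "MCI"]
        cn = wide[wide["group"] == "CN"]
        t_ref, _ = sps.ttest_ind(cn["open"], mci["open"])  # groups sorted
        assert se.loc["CN vs MCI @ open", "statistic"] == pytest.approx(t_ref)
        t_ref, _ = sps.ttest_rel(mci["closed"], mci["open"])
        assert se.loc["closed vs open @ MCI", "statistic"] == pytest.approx(t_ref)


class TestMultiplicity:
    def test_fdr_equal_ps(self):
        assert np.allclose(fdr_bh([0.03, 0.03, 0.03]), 0.03)

    def test_fdr_stepup_hand_computed(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_fdr_dominates_raw_and_below_bonferroni(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= bonferroni(p) + 1e-12).all()

    def test_bonferroni_scaling_and_cap(self):
        assert bonferroni([0.01], m=3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], m=3)[0] == 1.0

    def test_bonferroni_family_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.01, 0.02, 0.03], m=2)

    def test_fdr_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestPearson:
    def test_perfect_linear(self, rng):
        x = rng.standard_normal(30)
        assert pearson_corr_test(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_corr_test(x, -x).r == pytest.approx(-1.0)

    @pytest.mark.parametrize("r,expected_p", [(-0.384, 0.025), (-0.427, 0.012)])
    def test_published_correlation_pairs(self, rng, r, expected_p):
        """Sample r values reported for n=34 reproduce their printed p."""
        x, y = exact_correlation_pair(rng, 34, r)
        res = pearson_corr_test(x, y)
        assert res.r == pytest.approx(r, abs=1e-9)
        assert round(res.p, 3) == expected_p

    def test_p_matches_t_formula(self, rng):
        x, y = exact_correlation_pair(rng, 50, 0.31)
        res = pearson_corr_test(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr_test(np.ones(10), np.arange(10.0))
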