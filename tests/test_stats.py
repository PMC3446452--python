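"""Statistics layer against hand-computed and closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ratgait import stats, synth
from ratgait.exceptions import InsufficientDataError, ParameterError


def t_cdf_df2(t):
    """Closed-form Student-t CDF for df = 2."""
    return 0.5 + t / (2.0 * math.sqrt(t * t + 2.0))


class TestOneSampleRepeatedT:
    def test_constant_sample_at_null(self):
        res = stats.one_sample_repeated_t([0.5, 0.5, 0.5], 0.5)
        assert (res.t, res.p) == (0.0, 1.0)

    def test_df2_closed_form(self):
        res = stats.one_sample_repeated_t([0.52, 0.54, 0.50], 0.5)
        assert res.t == pytest.approx(math.sqrt(3.0), abs=1e-9)
        assert res.df == 2
        expected_p = 2.0 * (1.0 - t_cdf_df2(math.sqrt(3.0)))
        assert res.p == pytest.approx(expected_p, abs=1e-9)
        assert res.p == pytest.approx(0.2254, abs=5e-5)

    def test_shift_invariance(self):
        a = stats.one_sample_repeated_t([0.52, 0.54, 0.50], 0.5)
        b = stats.one_sample_repeated_t([1.52, 1.54, 1.50], 1.5)
        assert (a.t, a.p) == pytest.approx((b.t, b.p))

    def test_degenerate_sample_off_null_flagged(self):
        res = stats.one_sample_repeated_t([0.6, 0.6], 0.5)
        assert res.degenerate and res.p == 0.0

    def test_single_animal_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.one_sample_repeated_t([0.5], 0.5)


class TestFactorialAnova:
    def test_hand_computed_one_factor(self):
        # groups {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5 on (1,4)
        df = pd.DataFrame({"value": [1, 2, 3, 4, 5, 6],
                           "group": list("AAABBB")})
        table = stats.factorial_anova(df, "value", ["group"])
        row = table[table.term == "group"].iloc[0]
        assert row["sum_sq"] == pytest.approx(13.5)
        assert row["F"] == pytest.approx(13.5)
        assert (row["df"], table[table.term == "Residual"].iloc[0]["df"]) \
            == (1.0, 4.0)

    def test_identical_groups_give_null_result(self):
        df = pd.DataFrame({"value": [2.0] * 6, "group": list("AAABBB")})
        table = stats.factorial_anova(df, "value", ["group"])
        row = table[table.term == "group"].iloc[0]
        assert (row["F"], row["p"]) == (0.0, 1.0)

    def test_two_factor_terms_present(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "value": rng.normal(size=24),
            "group": np.repeat(["a", "b", "c"], 8),
            "day": np.tile([9, 23], 12)})
        table = stats.factorial_anova(df, "value", ["group", "day"])
        assert set(table.term) == {"group", "day", "group:day", "Residual"}

    def test_label_permutation_preserves_null_distribution(self):
        rng = np.random.default_rng(1)
        f_orig, f_perm = [], []
        for _ in range(60):
            df = pd.DataFrame({"value": rng.normal(size=18),
                               "group": np.repeat(["a", "b", "c"], 6)})
            table = stats.factorial_anova(df, "value", ["group"])
            f_orig.append(table[table.term == "group"].iloc[0]["F"])
            permuted = df.assign(group=rng.permutation(df["group"]))
            table = stats.factorial_anova(permuted, "value", ["group"])
            f_perm.append(table[table.term == "group"].iloc[0]["F"])
        ks = sps.ks_2samp(f_orig, f_perm)
        assert ks.pvalue > 0.01


class TestTukeyHSD:
    def test_two_groups_match_pooled_t_test(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.5, 6.0]
        pairs = stats.tukey_hsd(a, b)
        t_p = sps.ttest_ind(a, b).pvalue
        assert pairs.iloc[0]["p"] == pytest.approx(t_p, abs=1e-4)

    def test_identical_groups_are_null(self):
        pairs = stats.tukey_hsd([2.0, 2.0], [2.0, 2.0], [2.0, 2.0])
        assert (pairs["p"] == 1.0).all()

    def test_separated_group_dominates(self):
        rng = np.random.default_rng(2)
        jitter = lambda v: [v + 1e-3 * rng.normal() for _ in range(3)]
        pairs = stats.tukey_hsd(jitter(1.0), jitter(1.0), jitter(5.0),
                                labels=["a", "b", "c"])
        by_pair = pairs.set_index(["group1", "group2"])["p"]
        assert by_pair[("a", "c")] < 1e-6
        assert by_pair[("b", "c")] < 1e-6
        assert by_pair[("a", "b")] > 0.5

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ParameterError):
            stats.tukey_hsd([1.0, 2.0])


class TestAncovaVelocity:
    @staticmethod
    def build(with_velocity_effect=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group in ("naive", "sham", "operated"):
            for day in (9, 23):
                for animal in range(4):
                    v = rng.uniform(30, 50)
                    value = 0.3 * v if with_velocity_effect \
                        else rng.normal(10, 1)
                    rows.append((group, day, v, value))
        return pd.DataFrame(rows, columns=["group", "day", "velocity",
                                           "value"])

    def test_recovers_constructed_velocity_slope(self):
        df = self.build(with_velocity_effect=True)
        res = stats.ancova_velocity(df)
        assert res.velocity_slope == pytest.approx(0.3, abs=1e-9)
        row = res.anova[res.anova.term == "group"].iloc[0]
        assert (row["F"], row["p"]) == (0.0, 1.0)

    def test_velocity_shift_changes_only_intercept(self):
        df = self.build(with_velocity_effect=True)
        shifted = df.assign(velocity=df["velocity"] + 100.0)
        a = stats.ancova_velocity(df)
        b = stats.ancova_velocity(shifted)
        assert b.velocity_slope == pytest.approx(a.velocity_slope)
        pd.testing.assert_frame_equal(a.anova, b.anova, check_exact=False)

    def test_constant_velocity_drops_covariate(self):
        df = self.build(with_velocity_effect=False)
        df["velocity"] = 40.0
        with pytest.warns(UserWarning, match="constant"):
            res = stats.ancova_velocity(df)
        assert res.covariate_dropped and res.velocity_slope is None


class TestKruskalWallis:
    def test_tie_corrected_hand_case(self):
        # ranks {1.5, 1.5, 3, 4}: H = 2.4, tie factor 0.9 -> 2.667
        h, p = stats.kruskal_wallis([0, 0], [4, 5])
        assert h == pytest.approx(2.6667, abs=5e-5)

    def test_identical_values_are_null(self):
        assert stats.kruskal_wallis([3, 3], [3, 3, 3]) == (0.0, 1.0)

    def test_invariant_under_monotone_transform(self):
        a, b, c = [0, 1, 2], [2, 3, 4], [4, 5, 6]
        h1, _ = stats.kruskal_wallis(a, b, c)
        f = lambda g: [math.exp(x) for x in g]
        h2, _ = stats.kruskal_wallis(f(a), f(b), f(c))
        assert h1 == pytest.approx(h2, abs=1e-12)


class TestCytokineCompare:
    @staticmethod
    def panel(values_by_group, analyte="il6", below=None):
        rows = []
        i = 0
        for group, values in values_by_group.items():
            for v in values:
                rows.append((f"a{i}", group, analyte, v,
                             below[i] if below else False))
                i += 1
        return pd.DataFrame(rows, columns=["animal", "group", "analyte",
                                           "value", "below_detection"])

    def test_lognormal_values_are_gated_into_log10(self):
        rng = np.random.default_rng(3)
        df = self.panel({g: 10 ** rng.normal(2, 0.8, 12)
                         for g in ("naive", "sham", "operated")})
        summary, _ = stats.cytokine_compare(df)
        row = summary.iloc[0]
        assert row["status"] == "tested"
        assert row["shapiro_p"] < 0.05 and row["log_transformed"]

    def test_all_below_detection_is_untestable(self):
        df = self.panel({"naive": [np.nan] * 3, "sham": [np.nan] * 3},
                        below=[True] * 6)
        summary, pairwise = stats.cytokine_compare(df)
        assert summary.iloc[0]["status"] == "untestable_all_below_detection"
        assert pairwise.empty

    def test_detectability_percentage_reported(self):
        df = self.panel({"naive": [100.0, 120.0, np.nan, 90.0],
                         "sham": [110.0, np.nan, 95.0, 100.0]},
                        below=[False, False, True, False,
                               False, True, False, False])
        summary, _ = stats.cytokine_compare(df)
        assert summary.iloc[0]["pct_detectable"] == pytest.approx(75.0)

    def test_normality_gate_passes_after_log_transform(self):
        # log-normal groups: raw values fail the gate, log10 values pass
        rng = np.random.default_rng(4)
        passes = 0
        for _ in range(100):
            raw = 10 ** rng.normal(2, 0.6, 30)
            if sps.shapiro(np.log10(raw)).pvalue >= 0.05:
                passes += 1
        assert passes > 90


class TestRegression:
    def test_perfect_line(self):
        res = stats.univariate_regression([1, 2, 3], [2, 4, 6])
        assert res.beta0 == pytest.approx(0.0, abs=1e-12)
        assert res.beta1 == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_pattern_has_zero_slope(self):
        res = stats.univariate_regression([0, 1, 2], [0, 1, 0])
        assert res.beta1 == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_flagged(self):
        res = stats.univariate_regression([2, 2, 2], [1, 2, 3])
        assert res.flag == "constant_x" and math.isnan(res.beta1)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(size=30)
        res = stats.univariate_regression(x, y)
        r = sps.pearsonr(x, y).statistic
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_correlation_table_shape_and_adjustment(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame({
            "symmetry": rng.normal(0.5, 0.02, 16),
            "balance": rng.normal(0, 1, 16),
            "lesion": rng.normal(10, 3, 16),
            "oarsi": rng.integers(0, 6, 16).astype(float)})
        table = stats.correlation_table(data, ["symmetry", "balance"],
                                        ["lesion", "oarsi"], adjust="bh")
        assert len(table) == 4
        assert {"r_squared", "beta1", "se_beta1", "p", "p_adj"} <= \
            set(table.columns)
        assert (table["p_adj"] >= table["p"] - 1e-12).all()


class TestPairedLimbTests:
    def test_paired_t_with_bonferroni(self):
        rows = []
        rng = np.random.default_rng(7)
        for day in (9, 16, 23):
            for i in range(6):
                base = rng.normal(12, 1)
                rows.append((f"a{i}", day, "LH", base))
                rows.append((f"a{i}", day, "RH", base - 4.0
                             + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["animal", "day", "limb", "value"])
        table = stats.paired_limb_tests(df)
        assert len(table) == 3
        assert (table["mean_diff"] < 0).all()
        assert (table["p_bonferroni"] >= table["p"] - 1e-15).all()
        assert (table["p_bonferroni"] <= 1.0).all()
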