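import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegdiv import (
    PowerAnalysisSpec,
    bootstrap_band_difference,
    cell_tests,
    cohens_f_from_eta2,
    covariate_correlation,
    rm_anova_two_level,
    rm_power,
)

from .oracles import bh_adjust_brute


class TestRmAnova:
    def test_identical_conditions_null_result(self, rng):
        x = rng.standard_normal(10)
        res = rm_anova_two_level(x, x.copy())
        assert res.F == 0.0
        assert res.partial_eta2 == 0.0
        assert res.p == 1.0

    def test_degrees_of_freedom_at_n28(self, rng):
        res = rm_anova_two_level(rng.standard_normal(28), rng.standard_normal(28))
        assert (res.df1, res.df2) == (1, 27)

    def test_equals_squared_paired_t(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        res = rm_anova_two_level(a, b)
        t_stat, t_p = sps.ttest_rel(a, b)
        assert res.F == pytest.approx(t_stat**2, abs=1e-10)
        assert res.p == pytest.approx(t_p, abs=1e-12)

    def test_matches_pingouin_glm(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = rng.standard_normal(12), rng.standard_normal(12) + 0.4
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "cond": ["a", "b"] * 12,
                "value": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pingouin.rm_anova(
            data=long, dv="value", within="cond", subject="subject",
            detailed=True, effsize="np2",
        )
        res = rm_anova_two_level(a, b)
        assert res.F == pytest.approx(float(ref.loc[0, "F"]), rel=1e-9)
        assert res.p == pytest.approx(float(ref.loc[0, "p_unc"]), rel=1e-9)
        assert res.partial_eta2 == pytest.approx(float(ref.loc[0, "np2"]), abs=1e-9)

    def test_unpaired_or_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            rm_anova_two_level(rng.standard_normal(5), rng.standard_normal(4))
        with pytest.raises(ValueError):
            rm_anova_two_level([1.0, 2.0], [1.5, 2.5])


class TestEffectSizeConversion:
    def test_map_endpoints(self):
        assert cohens_f_from_eta2(0.0) == 0.0
        assert cohens_f_from_eta2(0.5) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cohens_f_from_eta2(1.0)
        with pytest.raises(ValueError):
            cohens_f_from_eta2(-0.1)


class TestRmPower:
    def test_null_effect_gives_alpha(self):
        assert rm_power(PowerAnalysisSpec(f=0.0, n_total=14)) == pytest.approx(0.05)

    def test_monotone_in_n_and_f(self):
        powers_n = [rm_power(PowerAnalysisSpec(f=0.3, n_total=n)) for n in (8, 16, 32)]
        assert powers_n == sorted(powers_n)
        powers_f = [rm_power(PowerAnalysisSpec(f=f, n_total=20)) for f in (0.1, 0.3, 0.6)]
        assert powers_f == sorted(powers_f)
        assert rm_power(PowerAnalysisSpec(f=5.0, n_total=20)) > 0.9999

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            PowerAnalysisSpec(f=0.3, n_total=2, n_groups=2)
        with pytest.raises(ValueError):
            PowerAnalysisSpec(f=0.3, n_total=14, corr_among_measures=1.0)

    def test_predicts_simulated_rejection_rate(self, rng):
        # paired design: noncentrality N*d^2 matches f = d * sqrt((1-rho)/m)
        n, d, reps = 28, 0.55, 600
        rejections = 0
        for _ in range(reps):
            diff = rng.standard_normal(n) + d
            res = rm_anova_two_level(diff, np.zeros(n))
            rejections += res.p < 0.05
        predicted = rm_power(PowerAnalysisSpec(f=d / 2.0, n_total=n))
        assert rejections / reps == pytest.approx(predicted, abs=0.10)


class TestCellTests:
    def test_adjusted_p_matches_brute_force_bh(self, rng):
        diffs = pd.DataFrame(
            rng.standard_normal((10, 24)) + np.linspace(0, 1.2, 24)[None, :]
        )
        table = cell_tests(diffs)
        np.testing.assert_allclose(
            table["p_fdr"], bh_adjust_brute(table["p"]), atol=1e-12
        )

    def test_adjusted_monotone_in_raw_rank(self, rng):
        table = cell_tests(pd.DataFrame(rng.standard_normal((8, 30))))
        ordered = table.sort_values("p")
        assert (np.diff(ordered["p_fdr"]) >= -1e-15).all()
        assert (table["p_fdr"] >= table["p"] - 1e-15).all()

    def test_flags_consistent_with_adjusted_threshold(self, rng):
        diffs = pd.DataFrame(rng.standard_normal((12, 20)) + 0.8)
        table = cell_tests(diffs, alpha=0.05)
        np.testing.assert_array_equal(table["significant"], table["p_fdr"] <= 0.05)
        if table["significant"].any():
            max_flagged_raw = table.loc[table["significant"], "p"].max()
            assert not (
                (table["p"] > max_flagged_raw) & table["significant"]
            ).any()

    def test_null_cells_unflagged_and_zero_variance_warned(self, rng):
        diffs = pd.DataFrame(rng.standard_normal((6, 10)) * 1e-12)
        diffs[0] = 5.0  # constant column: zero variance
        with pytest.warns(UserWarning, match="zero-variance"):
            table = cell_tests(diffs)
        assert table.loc[0, "p"] == 1.0

    def test_multiindex_columns_preserved(self, rng):
        cols = pd.MultiIndex.from_product(
            [["O1", "O2"], ["alpha", "beta1"]], names=["channel", "band"]
        )
        table = cell_tests(pd.DataFrame(rng.standard_normal((5, 4)), columns=cols))
        assert table.index.names == ["channel", "band"]


class TestBootstrapBandDifference:
    def freqs(self):
        return np.arange(1.0, 40.5, 0.5)

    def test_zero_differences_never_significant(self):
        freqs = self.freqs()
        diffs = pd.DataFrame(np.zeros((6, len(freqs))), columns=freqs)
        table = bootstrap_band_difference(diffs, n_boot=500, seed=1)
        assert not table["significant"].any()

    def test_planted_alpha_shift_detected_in_band(self, rng):
        freqs = self.freqs()
        values = rng.standard_normal((12, len(freqs))) * 0.5
        alpha_bins = (freqs >= 8.0) & (freqs < 12.5)
        values[:, alpha_bins] += 3.0
        table = bootstrap_band_difference(
            pd.DataFrame(values, columns=freqs), n_boot=1000, seed=2
        )
        sig = table[table["significant"]]
        assert len(sig) > 0
        in_alpha = (sig["freq_hz"] >= 8.0) & (sig["freq_hz"] < 12.5)
        # every planted bin is detected, and detections concentrate in-band
        assert in_alpha.sum() == alpha_bins.sum()
        assert in_alpha.mean() > 0.5

    def test_deterministic_for_fixed_seed(self, rng):
        freqs = self.freqs()
        diffs = pd.DataFrame(rng.standard_normal((5, len(freqs))), columns=freqs)
        a = bootstrap_band_difference(diffs, n_boot=300, seed=9)
        b = bootstrap_band_difference(diffs, n_boot=300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_p_values_use_finite_sample_convention(self):
        freqs = self.freqs()
        diffs = pd.DataFrame(np.ones((5, len(freqs))) * 2.0, columns=freqs)
        table = bootstrap_band_difference(diffs, n_boot=500, seed=0)
        assert (table["p"] >= 2.0 / 501.0 - 1e-12).all()

    def test_too_few_bootstraps_rejected(self, rng):
        diffs = pd.DataFrame(rng.standard_normal((5, 4)))
        with pytest.raises(ValueError):
            bootstrap_band_difference(diffs, n_boot=50)


class TestCovariateCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = covariate_correlation(x, 3.0 * x + 1.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_null_p_matches_permutation_oracle(self, rng):
        x = rng.standard_normal(28)
        y = rng.permutation(x)
        r, p = covariate_correlation(x, y)
        assert abs(r) < 0.5
        perm_rs = np.array(
            [abs(np.corrcoef(x, rng.permutation(y))[0, 1]) for _ in range(2000)]
        )
        perm_p = (perm_rs >= abs(r)).mean()
        assert p == pytest.approx(perm_p, abs=0.05)

    def test_affine_invariance(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r1, p1 = covariate_correlation(x, y)
        r2, p2 = covariate_correlation(5.0 * x - 2.0, 0.1 * y + 7.0)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            covariate_correlation(np.ones(10), np.arange(10.0))
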