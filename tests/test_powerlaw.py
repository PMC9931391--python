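"""Truncated power-law machinery: outliers, MLE, goodness-of-fit, range."""

import numpy as np
import pytest
from scipy import integrate, stats

from scalefree import (
    PowerLawFit,
    TAU_GRID,
    exponent_uncertainty,
    fit_power_law_range,
    goodness_of_fit,
    remove_outliers,
    sample_truncated_powerlaw,
    truncated_mle_exponent,
    binned_pdf_envelope,
)
from scalefree.powerlaw import truncated_powerlaw_logpdf


class TestRemoveOutliers:
    def test_log_dense_sequence_unchanged(self):
        sizes = np.geomspace(1.0, 100.0, 300)  # all log gaps far below 3% of range
        assert np.array_equal(remove_outliers(sizes), np.sort(sizes))

    def test_arithmetic_head_is_sparse_in_log_and_peeled(self):
        # 1, 2, 3, ... is log-sparse at the head: the gap 1 -> 2 is 0.3
        # decades, far above 3% of the 2-decade range, so the first few
        # samples count as outliers under the gap rule
        sizes = np.arange(1.0, 101.0)
        out = remove_outliers(sizes)
        assert out[0] > 1.0
        assert out[-1] == 100.0
        assert out.size > 90

    def test_single_distant_sample_removed(self):
        sizes = np.concatenate([np.arange(1.0, 10.1, 0.1), [1e6]])
        out = remove_outliers(sizes)
        assert out[-1] == pytest.approx(10.0)
        assert out.size == sizes.size - 1

    def test_successive_isolated_extremes_removed(self):
        sizes = np.concatenate([np.arange(1.0, 10.1, 0.1), [1e5, 1e6]])
        out = remove_outliers(sizes)
        assert out[-1] == pytest.approx(10.0)

    def test_head_outlier_removed(self):
        sizes = np.concatenate([[1e-6], np.arange(1.0, 10.1, 0.1)])
        out = remove_outliers(sizes)
        assert out[0] == pytest.approx(1.0)

    def test_uniform_log_gaps_at_or_below_threshold_unchanged(self):
        # a geometric sequence has uniform log gaps; when the threshold
        # matches them (strict inequality) nothing is removed
        sizes = np.logspace(0, 3, 11)  # gaps of 0.3 decades over 3 decades
        out = remove_outliers(sizes, gap_frac=0.101)
        assert np.allclose(out, sizes)

    def test_fewer_than_three_unchanged(self):
        assert np.array_equal(remove_outliers(np.array([5.0, 1.0])), [1.0, 5.0])

    def test_duplicated_head_block_not_treated_as_outlier(self):
        # quantized data: a big log-gap adjacent to a *block* of duplicates
        # must not delete the block
        sizes = np.concatenate([np.full(500, 0.0025), np.full(300, 0.005),
                                np.geomspace(0.0075, 10.0, 500)])
        out = remove_outliers(sizes)
        assert out.size == sizes.size

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.array([0.0, 1.0, 2.0]))


class TestTruncatedMLE:
    def test_normalization_over_grid(self):
        for tau in [0.7, 1.0, 1.36, 2.0]:
            val, _ = integrate.quad(
                lambda s: np.exp(truncated_powerlaw_logpdf(s, tau, 2.0, 500.0)), 2.0, 500.0
            )
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(5)
        sizes = sample_truncated_powerlaw(400, 1.34, 1.0, 1e3, rng)
        tau, logl = truncated_mle_exponent(sizes, 1.0, 1e3)
        # independent brute force straight from the density formula
        tail = sizes[(sizes >= 1.0) & (sizes <= 1e3)]
        best_tau, best_ll = None, -np.inf
        for t in TAU_GRID:
            if abs(t - 1.0) < 1e-12:
                c = 1.0 / np.log(1e3)
            else:
                c = (1.0 - t) / (1e3 ** (1.0 - t) - 1.0)
            ll = float(np.sum(np.log(c) - t * np.log(tail)))
            if ll > best_ll:
                best_tau, best_ll = t, ll
        assert tau == best_tau
        assert logl == pytest.approx(best_ll)

    def test_recovers_known_exponent(self):
        rng = np.random.default_rng(7)
        sizes = sample_truncated_powerlaw(10_000, 1.5, 1.0, 1e4, rng)
        tau, _ = truncated_mle_exponent(sizes, 1.0, 1e4)
        assert tau == pytest.approx(1.5, abs=0.04)

    def test_tau_one_branch_wins_on_tau_one_samples(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(5):
            sizes = sample_truncated_powerlaw(5000, 1.0, 1.0, 1e3, rng)
            tau, _ = truncated_mle_exponent(sizes, 1.0, 1e3)
            wins += abs(tau - 1.0) <= 0.02
        assert wins >= 4

    def test_insufficient_tail_errors(self):
        with pytest.raises(ValueError, match="insufficient tail"):
            truncated_mle_exponent(np.array([1.0, 10.0]), 1.0, 10.0)
        with pytest.raises(ValueError):
            truncated_mle_exponent(np.ones(20), 5.0, 2.0)  # s_min >= s_max


class TestGoodnessOfFit:
    def test_self_consistency_near_one(self):
        rng = np.random.default_rng(13)
        high = 0
        for _ in range(10):
            sizes = sample_truncated_powerlaw(1000, 1.5, 1.0, 1e3, rng)
            fit = PowerLawFit(1.5, 1.0, 1e3, 3.0, 0.0, sizes.size)
            F = goodness_of_fit(sizes, fit, rng_seed=rng)
            high += F >= 0.9
        assert high >= 8  # surrogate draws almost always fit themselves

    def test_exponential_misfit_rejected(self):
        rng = np.random.default_rng(17)
        sizes = 1.0 + rng.exponential(30.0, 1000)
        sizes = sizes[(sizes >= 1.0) & (sizes <= 1e3)]
        tau, _ = truncated_mle_exponent(sizes, 1.0, 1e3)
        fit = PowerLawFit(tau, 1.0, 1e3, 3.0, 0.0, sizes.size)
        F = goodness_of_fit(sizes, fit, rng_seed=rng)
        assert F < 0.75

    def test_zero_surrogates_invalid(self):
        fit = PowerLawFit(1.5, 1.0, 100.0, 2.0, 0.0, 50)
        with pytest.raises(ValueError):
            goodness_of_fit(np.geomspace(1, 100, 50), fit, n_surrogate=0)


class TestFitPowerLawRange:
    def test_known_truth_recovery(self):
        rng = np.random.default_rng(19)
        sizes = sample_truncated_powerlaw(10_000, 1.5, 1.0, 1e4, rng)
        fit = fit_power_law_range(sizes, rng_seed=rng)
        assert fit.range_decades == pytest.approx(4.0, abs=0.3)
        assert fit.tau == pytest.approx(1.5, abs=0.05)
        assert fit.F >= 0.80

    def test_lognormal_impostor_small_range(self):
        rng = np.random.default_rng(23)
        sizes = 10 ** rng.normal(1.0, 0.3, 1000)  # sigma 0.3 in log10
        fit = fit_power_law_range(sizes, rng_seed=rng)
        assert fit.range_decades <= 1.5

    def test_identical_sizes_zero_range(self):
        fit = fit_power_law_range(np.full(100, 2.5), rng_seed=0)
        assert fit.range_decades == 0.0
        assert np.isnan(fit.tau)

    def test_too_few_sizes_zero_range(self):
        fit = fit_power_law_range(np.geomspace(1, 100, 10), rng_seed=0)
        assert fit.range_decades == 0.0

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(29)
        sizes = sample_truncated_powerlaw(3000, 1.4, 1.0, 1e3, rng)
        a = fit_power_law_range(sizes, rng_seed=31)
        b = fit_power_law_range(sizes * 137.0, rng_seed=31)
        assert b.range_decades == pytest.approx(a.range_decades)
        assert b.tau == a.tau
        assert b.s_min == pytest.approx(a.s_min * 137.0, rel=1e-9)
        assert b.s_max == pytest.approx(a.s_max * 137.0, rel=1e-9)

    def test_stricter_criterion_never_widens_range(self):
        rng = np.random.default_rng(37)
        sizes = sample_truncated_powerlaw(2000, 1.3, 1.0, 1e3, rng)
        sizes = np.concatenate([sizes, 10 ** rng.normal(0.5, 0.4, 500)])  # contaminate
        loose = fit_power_law_range(sizes, F_criterion=0.75, rng_seed=41)
        strict = fit_power_law_range(sizes, F_criterion=0.90, rng_seed=41)
        assert strict.range_decades <= loose.range_decades + 1e-12

    def test_type_one_behavior(self):
        # on genuine truncated power laws the fitter finds nearly the full range
        rng = np.random.default_rng(43)
        good = 0
        for _ in range(10):
            sizes = sample_truncated_powerlaw(10_000, 1.5, 1.0, 1e4, rng)
            fit = fit_power_law_range(sizes, rng_seed=rng)
            good += fit.range_decades >= 3.5
        assert good > 9


class TestExponentUncertainty:
    def test_magnitude_and_shrinkage_with_n(self):
        rng = np.random.default_rng(3)
        tau_vars = {}
        for n in [100, 1000, 10_000]:
            sizes = sample_truncated_powerlaw(n, 1.5, 1.0, 1e3, rng)
            fit = fit_power_law_range(sizes, rng_seed=rng)
            if not fit.ok:
                fit = PowerLawFit(1.5, 1.0, 1e3, 3.0, 1.0, n)
            tau_vars[n] = exponent_uncertainty(sizes, fit, rng_seed=rng)
        assert tau_vars[100] > tau_vars[1000] > tau_vars[10_000]
        assert 0.01 <= tau_vars[1000] <= 0.25

    def test_requires_valid_fit(self):
        no_fit = PowerLawFit(np.nan, 1.0, 1.0, 0.0, 0.0, 0)
        with pytest.raises(ValueError):
            exponent_uncertainty(np.geomspace(1, 100, 100), no_fit)

    def test_envelope_hook_brackets_true_density(self):
        rng = np.random.default_rng(47)
        sizes = sample_truncated_powerlaw(2000, 1.5, 1.0, 1e3, rng)
        fit = PowerLawFit(1.5, 1.0, 1e3, 3.0, 1.0, sizes.size)
        env = binned_pdf_envelope(sizes, fit, rng_seed=rng)
        true_pdf = np.exp(truncated_powerlaw_logpdf(env["centers"], 1.5, 1.0, 1e3))
        inside = (true_pdf >= env["lower"]) & (true_pdf <= env["upper"])
        assert inside.mean() > 0.8


class TestSampler:
    def test_tau_one_log_uniform(self):
        rng = np.random.default_rng(53)
        s = sample_truncated_powerlaw(10_000, 1.0, 1.0, 10.0, rng)
        ks = stats.kstest(np.log10(s), stats.uniform(loc=0, scale=1).cdf)
        assert ks.statistic < 0.02

    def test_cdf_endpoint(self):
        class ZeroRng:
            def random(self, n):
                return np.zeros(n)

        s = sample_truncated_powerlaw(1, 1.5, 2.0, 100.0, ZeroRng())
        assert s[0] == pytest.approx(2.0)

    def test_dkw_band_against_analytic_cdf(self):
        rng = np.random.default_rng(59)
        n = 10_000
        tau, lo, hi = 1.5, 1.0, 1e4
        s = np.sort(sample_truncated_powerlaw(n, tau, lo, hi, rng))
        a = 1.0 - tau
        cdf = (s**a - lo**a) / (hi**a - lo**a)
        emp = np.arange(1, n + 1) / n
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))  # 99% DKW band
        assert np.max(np.abs(cdf - emp)) < eps

    def test_mean_matches_analytic(self):
        rng = np.random.default_rng(61)
        n = 10_000
        for tau in [0.8, 1.0, 1.5, 2.0]:
            s = sample_truncated_powerlaw(n, tau, 1.0, 1e3, rng)
            mean_an, _ = integrate.quad(
                lambda x: x * np.exp(truncated_powerlaw_logpdf(x, tau, 1.0, 1e3)), 1.0, 1e3
            )
            se = s.std(ddof=1) / np.sqrt(n)
            assert abs(s.mean() - mean_an) < 3 * se

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_truncated_powerlaw(0, 1.5, 1.0, 10.0)
        with pytest.raises(ValueError):
            sample_truncated_powerlaw(5, 1.5, 10.0, 1.0)
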