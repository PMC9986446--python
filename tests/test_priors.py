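"""Prior specification, sampling and closed-form quantile oracles."""

import numpy as np
import pytest
from scipy import stats

from dehtp_pbpk.likelihood import _fast_logpdf, marginal_prior
from dehtp_pbpk.priors import (
    GLOBAL_PRIORS,
    LOCAL_PRIORS,
    PHYSIO_PRIORS,
    PriorSpec,
    normal_from_median_interval,
    sample_prior,
    summarise_prior,
    uniform_from_median_interval,
)


class TestSamplingAgainstClosedForm:
    """Sampled quantiles must converge to analytic quantile functions."""

    @pytest.mark.parametrize(
        "spec, dist",
        [
            (PriorSpec("u", "uniform", (1.0, 30.0)), stats.uniform(1.0, 29.0)),
            (PriorSpec("n", "normal", (30.0, 10.0)), stats.norm(30.0, 10.0)),
            (PriorSpec("h", "halfnormal", (10.0,)), stats.halfnorm(scale=10.0)),
            (
                PriorSpec("ln", "lognormal", (np.log(19.5), 0.43)),
                stats.lognorm(s=0.43, scale=19.5),
            ),
        ],
    )
    def test_quantiles_match_analytic(self, spec, dist):
        x = sample_prior(spec, 200_000, seed=3)
        for q in (0.1, 0.5, 0.9):
            scale = dist.ppf(0.9) - dist.ppf(0.1)
            assert np.quantile(x, q) == pytest.approx(dist.ppf(q), abs=0.01 * scale)

    def test_truncation_respected_and_renormalised(self):
        spec = PriorSpec("n", "normal", (0.0, 1.0)).truncated_at_percentiles(0.05, 0.95)
        x = sample_prior(spec, 100_000, seed=5)
        lo, hi = stats.norm.ppf(0.05), stats.norm.ppf(0.95)
        assert x.min() >= lo and x.max() <= hi
        # median of the symmetric truncation stays at the centre
        assert np.median(x) == pytest.approx(0.0, abs=0.02)
        assert spec.quantile(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_summarise_prior(self):
        x = sample_prior(PriorSpec("u", "uniform", (0.0, 1.0)), 200_000, seed=1)
        s = summarise_prior(x)
        assert s["median"] == pytest.approx(0.5, abs=0.01)
        assert s["q2.5"] == pytest.approx(0.025, abs=0.01)
        assert s["q97.5"] == pytest.approx(0.975, abs=0.01)


class TestPublishedPriorColumn:
    """The tabulated prior medians/intervals are reproduced by sampling."""

    def test_uniform_plasma_pc_prior(self):
        x = sample_prior(GLOBAL_PRIORS["Pbab"], 100_000, seed=11)
        assert np.median(x) == pytest.approx(15.5, abs=0.2)
        assert np.percentile(x, 2.5) == pytest.approx(1.725, abs=0.2)

    def test_gut_half_life_prior(self):
        x = sample_prior(GLOBAL_PRIORS["DEHTP_GUT_half_life"], 100_000, seed=12)
        assert np.median(x) == pytest.approx(30.13, abs=0.35)
        assert np.percentile(x, [2.5, 97.5]) == pytest.approx([10.67, 49.37], abs=0.6)

    def test_liver_half_life_half_normal_prior(self):
        x = sample_prior(GLOBAL_PRIORS["DEHTP_half_life"], 100_000, seed=13)
        # closed form: scale * Phi^-1(0.75)
        assert np.median(x) == pytest.approx(10.0 * stats.norm.ppf(0.75), abs=0.15)
        assert np.median(x) == pytest.approx(6.62, abs=0.25)

    def test_error_sd_prior_is_unit_half_normal(self):
        x = sample_prior(GLOBAL_PRIORS["sigma_5cx_U"], 100_000, seed=14)
        assert np.median(x) == pytest.approx(0.674, abs=0.02)
        assert np.percentile(x, 97.5) == pytest.approx(2.24, abs=0.05)


class TestBackSolvedPriors:
    def test_uniform_round_trip(self):
        spec = uniform_from_median_interval("x", 2.49, 0.12, 4.89)
        x = sample_prior(spec, 200_000, seed=2)
        assert np.median(x) == pytest.approx(2.49, abs=0.03)
        assert np.percentile(x, 2.5) == pytest.approx(0.12, abs=0.05)
        assert np.percentile(x, 97.5) == pytest.approx(4.89, abs=0.05)

    def test_negative_lower_bound_clamped(self):
        spec = uniform_from_median_interval("lag", 1.98, 0.11, 3.90)
        assert spec.params[0] == 0.0
        assert spec.params[1] == pytest.approx((3.90 - 0.11) / 0.95)

    def test_normal_round_trip(self):
        spec = normal_from_median_interval("q", 0.150, 0.089, 0.21)
        base = stats.norm(0.150, (0.21 - 0.089) / (2 * 1.959964))
        assert spec.quantile(0.5) == pytest.approx(0.150, abs=1e-9)
        # truncated at the untruncated law's 5th/95th percentiles
        assert spec.support[0] == pytest.approx(base.ppf(0.05))


class TestSpecValidation:
    def test_unsupported_family(self):
        with pytest.raises(ValueError, match="family"):
            PriorSpec("x", "beta", (1.0, 1.0))

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            PriorSpec("x", "uniform", (3.0, 1.0))
        with pytest.raises(ValueError):
            PriorSpec("x", "normal", (0.0, -1.0))
        with pytest.raises(ValueError):
            PriorSpec("x", "normal", (0.0, 1.0), trunc=(2.0, -2.0))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            sample_prior(GLOBAL_PRIORS["Pbab"], 0, seed=0)


class TestFastLogDensity:
    """The sampler's closed-form log-densities agree with the scipy route."""

    @pytest.mark.parametrize("name", list(GLOBAL_PRIORS) + list(LOCAL_PRIORS))
    def test_fast_matches_scipy(self, name):
        spec = marginal_prior(name)
        fast = _fast_logpdf(spec)
        true_lo, true_hi = spec.support
        lo = true_lo if np.isfinite(true_lo) else -10.0
        hi = true_hi if np.isfinite(true_hi) else lo + 50.0
        for x in np.linspace(lo + 1e-9, hi - 1e-9, 7):
            assert fast(float(x)) == pytest.approx(float(spec.logpdf(x)), rel=1e-10, abs=1e-10)
        if np.isfinite(true_hi):
            assert fast(true_hi + 1.0) == -np.inf
        if np.isfinite(true_lo):
            assert fast(true_lo - 1.0) == -np.inf
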