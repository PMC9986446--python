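"""Sampler behaviour, posterior summaries, bands and the 48-h table."""

import numpy as np
import pytest

from dehtp_pbpk.likelihood import CalibrationDataset, ParameterVector, VolunteerData
from dehtp_pbpk.mcmc import (
    Chain,
    MCMCConfig,
    compare_48h,
    load_chain,
    posterior_summary,
    predictive_band,
    run_mcmc,
    save_chain,
)
from dehtp_pbpk.priors import GLOBAL_PRIORS, LOCAL_PRIORS


def empty_volunteer(name="V1", bw=89.0):
    """A volunteer with no observations: the posterior is the prior."""
    v = VolunteerData(volunteer=name, dose_mg=52.2, body_weight=bw)
    for met in ("5OH", "2cx", "5cx"):
        v.t_start[met] = np.array([])
        v.t_end[met] = np.array([])
        v.rate[met] = np.array([])
    return v


@pytest.fixture(scope="module")
def short_chain(noisy_study):
    _, data, _, _ = noisy_study
    return run_mcmc(data, MCMCConfig(iterations=400, thin=4, seed=5))


class TestSampler:
    def test_identical_chains_under_fixed_seed(self, noisy_study):
        _, data, _, _ = noisy_study
        cfg = MCMCConfig(iterations=120, thin=4, seed=9)
        a = run_mcmc(data, cfg)
        b = run_mcmc(data, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.log_posterior, b.log_posterior)

    def test_retained_count_is_iterations_over_thin(self, short_chain):
        assert len(short_chain.samples) == 400 // 4

    def test_prior_only_chain_reproduces_prior_quantiles(self):
        data = CalibrationDataset([empty_volunteer()])
        chain = run_mcmc(data, MCMCConfig(iterations=40_000, thin=10, seed=2))
        s = posterior_summary(chain)
        # closed-form prior medians within generous random-walk MC error
        assert s.table.loc["Pbab", "median"] == pytest.approx(
            GLOBAL_PRIORS["Pbab"].median, abs=2.5
        )
        assert s.table.loc["FracDoseLymph[0]", "median"] == pytest.approx(
            LOCAL_PRIORS["FracDoseLymph"].median, abs=0.05
        )
        assert s.table.loc["DEHTP_half_life", "median"] == pytest.approx(
            GLOBAL_PRIORS["DEHTP_half_life"].median, abs=1.5
        )

    def test_acceptance_rates_reported(self, short_chain):
        assert set(short_chain.acceptance) == {"global", "sigma", "local0", "local1", "local2"}
        assert all(0.0 <= v <= 1.0 for v in short_chain.acceptance.values())


class TestPosteriorSummary:
    def _chain(self, samples, logp):
        n = samples.shape[1]
        names = ParameterVector.at_prior_medians(
            (n - 18) // 19
        ).names
        cfg = MCMCConfig(iterations=len(samples), thin=1, burn_in_fraction=0.0)
        return Chain(samples=samples, log_posterior=np.asarray(logp, float),
                     names=names, n_volunteers=(n - 18) // 19, config=cfg)

    def test_constant_chain_collapses(self):
        row = ParameterVector.at_prior_medians(1).values
        chain = self._chain(np.tile(row, (10, 1)), np.zeros(10))
        s = posterior_summary(chain)
        np.testing.assert_allclose(s.table["median"], row)
        np.testing.assert_allclose(s.mode.values, row)
        np.testing.assert_allclose(s.table["q2.5"], s.table["q97.5"])

    def test_two_point_chain_median_is_midpoint(self):
        row = ParameterVector.at_prior_medians(1).values
        samples = np.vstack([row, row + 1.0])
        chain = self._chain(samples, [0.0, 3.0])
        s = posterior_summary(chain)
        np.testing.assert_allclose(s.table["median"], row + 0.5)
        np.testing.assert_allclose(s.mode.values, row + 1.0)  # higher log-posterior

    def test_interval_ordering_and_absorbed_fraction(self, short_chain):
        s = posterior_summary(short_chain)
        assert (s.table["q2.5"] <= s.table["median"]).all()
        assert (s.table["median"] <= s.table["q97.5"]).all()
        af = s.absorbed_fraction
        assert len(af) == 3 and (af["median"] <= 1.0).all() and (af["median"] >= 0.0).all()


class TestPredictiveBand:
    def test_single_draw_band_collapses_onto_curve(self, noisy_study, short_chain):
        _, data, _, _ = noisy_study
        one = Chain(
            samples=short_chain.samples[-1:], log_posterior=short_chain.log_posterior[-1:],
            names=short_chain.names, n_volunteers=3,
            config=MCMCConfig(iterations=1, thin=1, burn_in_fraction=0.0),
        )
        grid = np.arange(0.0, 12.0 + 1e-9, 0.1)
        band = predictive_band(one, data, volunteer=1, output="5cx", grid=grid)
        np.testing.assert_allclose(band["lower"], band["mode"])
        np.testing.assert_allclose(band["upper"], band["mode"])

    def test_band_ordered_and_stable_under_subsampling(self, noisy_study, short_chain):
        _, data, _, _ = noisy_study
        grid = np.arange(0.0, 12.0 + 1e-9, 0.1)
        full = predictive_band(short_chain, data, 1, "5cx", grid=grid, max_draws=75)
        sub = predictive_band(short_chain, data, 1, "5cx", grid=grid, max_draws=40, seed=3)
        assert np.all(full["lower"] <= full["upper"] + 1e-15)
        scale = full["upper"].max()
        assert np.max(np.abs(full["upper"] - sub["upper"])) < 0.35 * scale


class TestCompare48h:
    def test_zero_noise_closure(self, zero_noise_study):
        _, data, truth, _ = zero_noise_study
        df = compare_48h(truth.parameter_vector(), data)
        rel = np.abs(df.measured_mg - df.predicted_mg) / df.predicted_mg
        assert rel.max() < 1e-3

    def test_empty_observations_give_zero_measured(self):
        df = compare_48h(
            ParameterVector.at_prior_medians(1),
            CalibrationDataset([empty_volunteer()]),
        )
        assert (df.measured_mg == 0.0).all() and (df.predicted_mg == 0.0).all()

    def test_noisy_discrepancy_comparable_to_injected_noise(self, noisy_study):
        design, data, truth, _ = noisy_study
        df = compare_48h(truth.parameter_vector(), data)
        for met, sd in design.noise_sd.items():
            sub = df[df.metabolite == met]
            # ~20 intervals of ~2.3 h: noise in the measured total has
            # SD ~ sd * sqrt(sum dt_i^2) < sd * 48 / sqrt(20)
            bound = 6.0 * sd * 48.0 / np.sqrt(20)
            assert np.abs(sub.measured_mg - sub.predicted_mg).max() < bound


class TestPersistence:
    def test_chain_round_trip(self, short_chain, tmp_path):
        save_chain(short_chain, tmp_path / "chain")
        back = load_chain(tmp_path / "chain")
        np.testing.assert_allclose(back.samples, short_chain.samples)
        np.testing.assert_allclose(back.log_posterior, short_chain.log_posterior)
        assert back.names == short_chain.names
        assert back.config.seed == short_chain.config.seed
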