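"""Sampler correctness: exact-conditional draws, conditional laws,
convergence diagnostics, and reproducibility contracts."""

import math

import numpy as np
import pytest
from scipy import stats

from nestmove.mcmc import (McmcConfig, _Accumulator, gelman_rubin,
                           initial_latents, run_mcmc, sample_locations,
                           sample_parameters, sample_states_ffbs,
                           update_alpha_sub_collapsed)
from nestmove.model import (ARS, FORAGING, TRAVELING, LatentState,
                            ModelParameters, ParameterError,
                            forward_loglik, process_mean)
from nestmove.simulate import SimulationConfig, dataset_to_tracks, simulate_dataset
from nestmove.tracks import TrackData

from .conftest import make_toy_track


def _scales() -> _Accumulator:
    from nestmove.mcmc import _DEFAULT_SCALES, _scalar_scale_names
    groups = _scalar_scale_names()
    scales = {k: _DEFAULT_SCALES[g] for k, g in groups.items()}
    return _Accumulator(scales, {k: 0.44 for k in scales})


def symmetric_params() -> ModelParameters:
    """All states exchangeable: transition logits 0, identical emissions."""
    return ModelParameters(
        gamma=np.array([0.3, 0.3]), theta=np.array([0.0, 0.0]),
        process_sd=np.array([4.0, 4.0]), alpha_top=np.zeros(2),
        alpha_sub=np.zeros((2, 2)), dive_mu=np.array([60.0, 60.0, 60.0]),
        dive_sd=np.array([30.0, 30.0, 30.0]))


class TestFfbs:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_marginal_matches_numpy_forward_recursion(self, params, seed):
        # two independent implementations of the same marginal likelihood
        track, y = make_toy_track(T=6, dive_intervals=(1, 2, 2, 5, 6, 6),
                                  depths=(30.0, 180.0, 25.0, 200.0, 15.0, 60.0),
                                  seed=seed)
        lat = LatentState(y, np.zeros(6, dtype=np.int64),
                          np.zeros(6, dtype=np.int64))
        ll = sample_states_ffbs(track, lat, params, np.random.default_rng(seed))
        expected = forward_loglik(track, y, params)
        assert abs(ll - expected) <= 1e-10 * abs(expected)

    def test_symmetric_model_gives_uniform_state_frequencies(self):
        p = symmetric_params()
        track, y = make_toy_track(T=3, dive_intervals=(1, 2, 3),
                                  depths=(50.0, 70.0, 60.0), n_fixes=0, seed=2)
        lat = LatentState(y, np.zeros(3, dtype=np.int64),
                          np.zeros(3, dtype=np.int64))
        rng = np.random.default_rng(10)
        n = 10_000
        top = np.zeros(3)
        sub = np.zeros(3)
        for _ in range(n):
            sample_states_ffbs(track, lat, p, rng)
            top += lat.s_top == TRAVELING
            sub += lat.s_sub == FORAGING
        se = 3 * math.sqrt(0.25 / n)
        assert np.all(np.abs(top / n - 0.5) < se)
        assert np.all(np.abs(sub / n - 0.5) < se)

    def test_overwhelming_emissions_pin_the_path(self):
        p = symmetric_params()
        p.dive_mu = np.array([20.0, 200.0, 20.0])
        p.dive_sd = np.array([5.0, 5.0, 5.0])
        track, y = make_toy_track(T=3, dive_intervals=(1, 2, 3),
                                  depths=(200.0, 200.0, 200.0), n_fixes=0,
                                  seed=3)
        lat = LatentState(y, np.zeros(3, dtype=np.int64),
                          np.zeros(3, dtype=np.int64))
        rng = np.random.default_rng(11)
        for _ in range(1000):
            sample_states_ffbs(track, lat, p, rng)
            assert np.all(lat.s_top == ARS)
            assert np.all(lat.s_sub == FORAGING)


class TestLocations:
    def _pinned_track(self):
        """Grid points 0 and 1 pinned by near-exact fixes; point 2 free."""
        track = TrackData(
            animal="a", track_id=1, t0=np.datetime64("2016-03-01", "s"),
            n_intervals=2,
            fix_interval=np.array([1, 1]), fix_j=np.array([0.0, 1.0]),
            fix_x=np.array([0.0, 10.0]), fix_y=np.array([0.0, 0.0]),
            fix_sd=np.array([1e-4, 1e-4]),
            dive_interval=np.zeros(0, dtype=np.int64), dive_depth=np.zeros(0))
        return track

    def test_unobserved_point_follows_process_law(self, params):
        track = self._pinned_track()
        lat = LatentState(np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 0.0]]),
                          np.array([TRAVELING, TRAVELING], dtype=np.int64),
                          np.zeros(0, dtype=np.int64))
        d = process_mean(np.array([10.0, 0.0]), np.zeros(2), TRAVELING, params)
        rng = np.random.default_rng(4)
        n = 100_000
        samples = np.empty((n, 2))
        for i in range(n):
            sample_locations(track, lat, params, 4.0, rng)
            samples[i] = lat.y[2]
        var = samples.var(axis=0, ddof=1)
        assert np.allclose(samples.mean(axis=0), d, atol=0.1)
        assert np.all(np.abs(var - params.process_sd ** 2) < 0.05
                      * params.process_sd ** 2)

    def test_precise_fixes_pin_locations(self, params):
        track = self._pinned_track()
        lat = LatentState(np.array([[5.0, 5.0], [5.0, 5.0], [10.0, 0.0]]),
                          np.array([TRAVELING, TRAVELING], dtype=np.int64),
                          np.zeros(0, dtype=np.int64))
        rng = np.random.default_rng(5)
        for scale in (2.0, 0.5, 0.1, 0.01, 1e-3, 1e-4):
            for _ in range(300):
                sample_locations(track, lat, params, scale, rng)
        assert np.hypot(*(lat.y[0] - [0.0, 0.0])) < 0.01
        assert np.hypot(*(lat.y[1] - [10.0, 0.0])) < 0.01

    def test_zero_width_proposal_always_accepted(self, params):
        track = self._pinned_track()
        lat = LatentState(np.zeros((3, 2)), np.zeros(2, dtype=np.int64),
                          np.zeros(0, dtype=np.int64))
        n_acc = sample_locations(track, lat, params, 0.0,
                                 np.random.default_rng(6))
        assert n_acc == 3  # symmetric proposal at equal density: ratio 1


class TestParameters:
    def _foraging_track(self, n_dives=1500, T=10):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(n_dives)
        depths = 190.0 + 40.0 * (z - z.mean()) / z.std(ddof=0)  # mean exactly 190
        per = n_dives // T
        dive_interval = np.repeat(np.arange(1, T + 1), per)
        depths = depths[: dive_interval.size]
        track = TrackData(
            animal="a", track_id=1, t0=np.datetime64("2016-03-01", "s"),
            n_intervals=T, fix_interval=np.zeros(0, dtype=np.int64),
            fix_j=np.zeros(0), fix_x=np.zeros(0), fix_y=np.zeros(0),
            fix_sd=np.zeros(0), dive_interval=dive_interval, dive_depth=depths)
        lat = LatentState(np.cumsum(rng.normal(0, 4, (T + 1, 2)), axis=0),
                          np.full(T, ARS, dtype=np.int64),
                          np.full(dive_interval.size, FORAGING, dtype=np.int64))
        return track, lat

    def test_all_foraging_dives_recover_sample_mean(self, params):
        track, lat = self._foraging_track()
        rng = np.random.default_rng(8)
        acc = _scales()
        mu = []
        for it in range(2500):
            sample_parameters([track], [lat], params, acc, rng)
            if it >= 500:
                mu.append(params.dive_mu[1])
        mu = np.asarray(mu)
        assert abs(mu.mean() - 190.0) < 2 * mu.std(ddof=1)

    def test_unoccupied_parameters_sample_their_priors(self, params):
        # single traveling interval, no dives: theta and the foraging mean
        # have no likelihood and must recover their uniform priors
        track = TrackData(
            animal="a", track_id=1, t0=np.datetime64("2016-03-01", "s"),
            n_intervals=1, fix_interval=np.array([1]), fix_j=np.array([0.5]),
            fix_x=np.array([0.0]), fix_y=np.array([0.0]),
            fix_sd=np.array([1.0]),
            dive_interval=np.zeros(0, dtype=np.int64), dive_depth=np.zeros(0))
        lat = LatentState(np.zeros((2, 2)), np.array([TRAVELING], dtype=np.int64),
                          np.zeros(0, dtype=np.int64))
        rng = np.random.default_rng(9)
        acc = _scales()
        theta_draws, mu_draws = [], []
        for it in range(32_000):
            sample_parameters([track], [lat], params, acc, rng)
            if it < 10_000:
                if (it + 1) % 100 == 0:
                    acc.adapt()
            elif it % 10 == 0:
                theta_draws.append(params.theta[1])
                mu_draws.append(params.dive_mu[1])
        theta_draws = np.asarray(theta_draws)[::2][:2000]
        mu_draws = np.asarray(mu_draws)[::2][:2000]
        p_theta = stats.kstest(theta_draws, stats.uniform(-math.pi,
                                                          2 * math.pi).cdf).pvalue
        p_mu = stats.kstest(mu_draws, stats.uniform(50.0, 200.0).cdf).pvalue
        assert p_theta > 0.01
        assert p_mu > 0.01

    def test_collapsed_logit_update_respects_prior_when_unoccupied(self, params):
        # no dives at all: the sub-layer logits must sample Normal(0, 2)
        track = TrackData(
            animal="a", track_id=1, t0=np.datetime64("2016-03-01", "s"),
            n_intervals=2, fix_interval=np.array([1]), fix_j=np.array([0.5]),
            fix_x=np.array([0.0]), fix_y=np.array([0.0]), fix_sd=np.array([1.0]),
            dive_interval=np.zeros(0, dtype=np.int64), dive_depth=np.zeros(0))
        lat = LatentState(np.zeros((3, 2)), np.zeros(2, dtype=np.int64),
                          np.zeros(0, dtype=np.int64))
        rng = np.random.default_rng(10)
        acc = _scales()
        draws = []
        for it in range(30_000):
            update_alpha_sub_collapsed([track], [lat], params, acc, rng)
            if it < 6000:
                if (it + 1) % 100 == 0:
                    acc.adapt()
            elif it % 12 == 0:
                draws.append(params.alpha_sub[0, 0])
        p = stats.kstest(np.asarray(draws)[:2000], stats.norm(0, 2.0).cdf).pvalue
        assert p > 0.01


class TestGelmanRubin:
    def test_matches_hand_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 50)) + np.array([[0.0], [0.5], [1.0]])
        res = gelman_rubin(x)
        w = np.mean(np.var(x, axis=1, ddof=1))
        b_over_n = np.var(x.mean(axis=1), ddof=1)
        expected = math.sqrt((49 / 50 * w + b_over_n) / w)
        assert abs(res.rhat - expected) < 1e-12

    def test_identical_constant_chains_flagged_degenerate(self):
        res = gelman_rubin(np.ones((2, 100)))
        assert res.degenerate

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        res = gelman_rubin(rng.standard_normal((2, 10_000)))
        assert 0.99 <= res.rhat <= 1.02

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 1000)) + np.array([[0.0], [100.0]])
        assert gelman_rubin(x).rhat > 10

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            gelman_rubin(np.ones((1, 100)))
        with pytest.raises(ParameterError):
            gelman_rubin(np.ones((2, 5)))


@pytest.fixture(scope="module")
def small_tracks():
    cfg = SimulationConfig(n_animals=1, steps_per_animal=30,
                           fixes_per_interval_rate=4.0,
                           dives_per_interval_rate=3.0, seed=19)
    return dataset_to_tracks(simulate_dataset(cfg))


class TestRunMcmc:
    def test_zero_retained_draws_rejected(self, small_tracks):
        with pytest.raises(ParameterError):
            run_mcmc(small_tracks, McmcConfig(n_iter=100, n_burnin=100))

    def test_empty_track_set_rejected(self):
        with pytest.raises(ParameterError):
            run_mcmc([], McmcConfig(n_iter=20, n_burnin=10))

    def test_same_seed_reproduces_draws_exactly(self, small_tracks):
        cfg = McmcConfig(n_chains=1, n_iter=120, n_burnin=60, thin=2, seed=42)
        a = run_mcmc(small_tracks, cfg)
        b = run_mcmc(small_tracks, cfg)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.s_top, b.s_top)
        assert np.array_equal(a.s_sub, b.s_sub)

    def test_chain_seeds_stable_under_added_chains(self, small_tracks):
        one = run_mcmc(small_tracks, McmcConfig(n_chains=1, n_iter=120,
                                                n_burnin=60, thin=2, seed=7))
        two = run_mcmc(small_tracks, McmcConfig(n_chains=2, n_iter=120,
                                                n_burnin=60, thin=2, seed=7))
        assert np.array_equal(one.params, two.params[two.chain == 0])

    def test_stored_draws_respect_support(self, small_tracks):
        draws = run_mcmc(small_tracks, McmcConfig(n_chains=1, n_iter=400,
                                                  n_burnin=100, thin=1, seed=3))
        p = draws.params
        names = draws.param_names
        col = {n: i for i, n in enumerate(names)}
        assert np.all(p[:, col["gamma_traveling"]] > p[:, col["gamma_ars"]])
        assert np.all((p[:, col["gamma_traveling"]] >= 0)
                      & (p[:, col["gamma_traveling"]] <= 1))
        assert np.all((p[:, col["dive_mu_foraging"]] >= 50)
                      & (p[:, col["dive_mu_foraging"]] <= 250))
        for name in ("dive_mu_traveling", "dive_mu_resting"):
            assert np.all((p[:, col[name]] >= 0) & (p[:, col[name]] <= 30))
        for name in names:
            if "sd" in name:
                assert np.all(p[:, col[name]] > 0)

    def test_acceptance_rates_within_adapted_bands(self, small_tracks):
        draws = run_mcmc(small_tracks, McmcConfig(n_chains=1, n_iter=1500,
                                                  n_burnin=1000, thin=1, seed=8))
        rates = draws.acceptance[0]
        assert 0.2 <= rates["loc_0"] <= 0.5

    def test_save_load_roundtrip(self, small_tracks, tmp_path):
        draws = run_mcmc(small_tracks, McmcConfig(n_chains=2, n_iter=80,
                                                  n_burnin=40, thin=2, seed=5))
        draws.save(tmp_path / "d")
        from nestmove.mcmc import PosteriorDraws

        loaded = PosteriorDraws.load(tmp_path / "d")
        assert np.allclose(loaded.params, draws.params)
        assert np.array_equal(loaded.s_top, draws.s_top)
        assert loaded.tracks[0].n_intervals == draws.tracks[0].n_intervals

    def test_initial_latents_are_deterministic(self, small_tracks):
        a = initial_latents(small_tracks)
        b = initial_latents(small_tracks)
        assert np.array_equal(a[0].y, b[0].y)
        assert np.array_equal(a[0].s_top, b[0].s_top)
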