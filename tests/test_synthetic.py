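"""Generators: determinism, rate/occupancy/dwell statistics, closed-form
oracles, latent-state contracts."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import fretdyn as fd
from fretdyn.correlator import PAIRS
from fretdyn.synthetic import sample_telegraph


def _small_photon_config(**kw):
    base = dict(n_molecules=8, duration=0.5, seed=42, triplet_fraction=0.0)
    base.update(kw)
    return fd.DiffusionSimConfig(**base)


class TestPhotonStreamGenerator:
    def test_determinism(self):
        s1 = fd.simulate_photon_stream(_small_photon_config())
        s2 = fd.simulate_photon_stream(_small_photon_config())
        np.testing.assert_array_equal(s1.times, s2.times)
        np.testing.assert_array_equal(s1.channels, s2.channels)
        s3 = fd.simulate_photon_stream(_small_photon_config(seed=43))
        assert len(s3) != len(s1) or not np.array_equal(s1.times, s3.times)

    def test_stream_contract(self):
        s = fd.simulate_photon_stream(_small_photon_config())
        assert np.all(np.diff(s.times) >= 0)
        assert s.times[0] >= 0 and s.times[-1] <= s.duration
        assert set(np.unique(s.channels)) <= {0, 1}

    def test_mean_rate_matches_profile_weighted_brightness(self):
        """Detected rate = N <W> q (1-f) per channel plus background, within
        3 standard errors (SE from block bootstrap of the binned counts —
        photon counts are over-dispersed because molecules correlate)."""
        cfg = _small_photon_config(
            n_molecules=30, duration=6.0, background_rate=500.0,
            triplet_fraction=0.28, time_step=5e-6, seed=7,
        )
        s = fd.simulate_photon_stream(cfg)
        for ch in (0, 1):
            t = s.channel_times(ch)
            blocks = np.histogram(t, bins=np.arange(0, cfg.duration + 0.05, 0.05))[0]
            rate = t.size / cfg.duration
            se = np.std(blocks, ddof=1) / 0.05 / np.sqrt(blocks.size)
            assert abs(rate - cfg.expected_count_rate(ch)) < 3 * se, ch

    def test_open_state_occupancy(self):
        cfg = _small_photon_config(n_molecules=20, duration=2.0,
                                   k_open=2250.0, k_close=2750.0, seed=9)
        s = fd.simulate_photon_stream(cfg)
        frac = s.metadata["latent"]["open_fraction"]
        # SE of a time-averaged telegraph: var ~ 2 p (1-p) tau_r / T per molecule
        p = cfg.p_open_eq
        se = np.sqrt(2 * p * (1 - p) * 200e-6 / (cfg.duration * cfg.n_molecules))
        assert abs(frac - p) < 3 * se

    def test_zero_contrast_requires_no_dynamics(self):
        with pytest.raises(ValueError, match="contrast"):
            _small_photon_config(
                brightness=((1e4, 1e4), (1e4, 1e4)), k_open=100.0, k_close=100.0
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            _small_photon_config(duration=-1.0)
        with pytest.raises(ValueError, match="n_molecules"):
            _small_photon_config(n_molecules=0)
        with pytest.raises(ValueError, match="time_step"):
            _small_photon_config(time_step=1e-3)  # cannot resolve the transit

    def test_crosstalk_moves_donor_photons(self):
        base = dict(n_molecules=20, duration=1.0, seed=3,
                    brightness=((40_000.0, 0.0), (40_000.0, 0.0)),
                    k_open=0.0, k_close=0.0)
        clean = fd.simulate_photon_stream(_small_photon_config(**base))
        leaky = fd.simulate_photon_stream(
            _small_photon_config(**base, crosstalk_beta=0.2)
        )
        assert clean.count_rate(1) == 0.0
        ratio = leaky.count_rate(1) / (leaky.count_rate(0) + leaky.count_rate(1))
        assert ratio == pytest.approx(0.2, abs=0.02)

    @staticmethod
    def _finite_box_correlation(cfg, tau):
        """Exact G(tau) for independent molecules diffusing in the periodic
        box with the 3D Gaussian detection profile: per-axis Fourier-mode
        sums of the wrapped diffusion propagator (independent oracle; it
        reduces to the standard 3D-Gaussian model as the box grows)."""
        tau = np.asarray(tau, dtype=float)
        mu, z0 = cfg.focus_lateral, cfg.axial_radius
        diff, n = cfg.diffusion_coeff, cfg.n_molecules
        S = np.ones_like(tau)
        mean2 = 1.0
        for h, r in zip(cfg.box_half_widths, (mu, mu, z0)):
            period = 2.0 * h
            k = 2 * np.pi * np.arange(-40, 41) / period
            a = np.sqrt(np.pi * r * r / 2.0) * np.exp(-((k * r) ** 2) / 8.0)
            S = S * ((a / period) ** 2 * np.exp(-diff * np.outer(tau, k**2))).sum(axis=1)
            mean2 *= (np.sqrt(np.pi * r * r / 2.0) / period) ** 2
        return (S - mean2) / (n * mean2)

    def test_box_oracle_converges_to_standard_model(self):
        """In a large box the finite-box oracle reproduces the standard
        3D-Gaussian diffusion model with N_eff, tau_D = mu^2/4D and p."""
        cfg = fd.DiffusionSimConfig(
            n_molecules=40, duration=1.0, seed=0,
            box_half_widths=(5.0, 5.0, 10.0),
            brightness=((30_000.0, 30_000.0), (30_000.0, 30_000.0)),
            k_open=0.0, k_close=0.0, triplet_fraction=0.0,
        )
        truth = fd.SeparateFitParams(
            n=cfg.effective_focus_molecules, tau_d=cfg.tau_d, p=cfg.aspect_ratio
        )
        tau = np.logspace(-6, np.log10(10 * cfg.tau_d), 40)
        np.testing.assert_allclose(
            self._finite_box_correlation(cfg, tau),
            fd.eval_separate(tau, truth, "CC"),
            rtol=0.01,
        )

    def test_single_species_matches_closed_form(self):
        """No switching, no triplet: the measured AC follows the closed-form
        correlation of the generator's own parameters within 5% rms over
        lags up to 10 tau_D.  The oracle is the exact finite-box model; at
        the default box it sits 2.6% below the infinite-volume amplitude
        (fixed molecule number) and cuts off the diffusion tail beyond ~1 ms
        (slowest periodic mode), both reproduced by the simulation."""
        cfg = fd.DiffusionSimConfig(
            n_molecules=40, duration=30.0, seed=3,
            brightness=((30_000.0, 30_000.0), (30_000.0, 30_000.0)),
            k_open=0.0, k_close=0.0, triplet_fraction=0.0,
        )
        s = fd.simulate_photon_stream(cfg)
        c = fd.smooth_curve(
            fd.multitau_correlate(s, "AC-d", base_resolution=2e-6, n_levels=18),
            3,
        )
        sel = (c.lags >= 1e-6) & (c.lags <= 10 * cfg.tau_d)
        model = self._finite_box_correlation(cfg, c.lags[sel])
        rel = (c.G[sel] - model) / model
        assert np.sqrt(np.mean(rel**2)) < 0.05


class TestTelegraph:
    def test_dwell_times_are_exponential(self):
        """KS test at alpha = 0.01 on ~1e4 dwells per state."""
        k_open, k_close = 2250.0, 2750.0
        times, states = sample_telegraph(k_open, k_close, duration=9.0, seed=8)
        dwells = np.diff(times)
        open_dwells = dwells[states[:-1] == 1]
        closed_dwells = dwells[states[:-1] == 0]
        assert min(open_dwells.size, closed_dwells.size) > 9_000
        for sample, k in ((open_dwells, k_close), (closed_dwells, k_open)):
            p = stats.kstest(sample, "expon", args=(0, 1.0 / k)).pvalue
            assert p > 0.01

    def test_occupancy_fraction(self):
        times, states = sample_telegraph(300.0, 700.0, duration=50.0, seed=1)
        bounds = np.append(times, 50.0)
        open_time = np.sum(np.diff(bounds)[states == 1])
        assert open_time / 50.0 == pytest.approx(0.3, abs=0.03)


class TestCurveSynthesis:
    def test_zero_noise_equals_model(self, apo_global, lags):
        curves = fd.synthesize_correlation_set(apo_global, lags, noise_sd=0.0)
        for pair in PAIRS:
            np.testing.assert_array_equal(
                curves[pair].G, fd.eval_global(lags, apo_global, pair)
            )

    def test_acd_amplitude_at_smallest_lag(self, apo_global):
        """At tau -> 0 the donor AC approaches
        (1 + alpha + beta) (1/N) / (1 - f)."""
        lag = np.array([1e-10])
        curves = fd.synthesize_correlation_set(apo_global, lag)
        expect = (1 + 0.13 + 0.12) / 9.11 / (1 - 0.282)
        assert curves["AC-d"].G[0] == pytest.approx(expect, rel=1e-4)

    def test_cc_pair_symmetry_and_noise_independence(self, apo_global, lags):
        noiseless = fd.synthesize_correlation_set(apo_global, lags)
        np.testing.assert_array_equal(noiseless["CC-da"].G, noiseless["CC-ad"].G)
        noisy = fd.synthesize_correlation_set(apo_global, lags, noise_sd=1e-3,
                                              seed=5)
        assert not np.array_equal(noisy["CC-da"].G, noisy["CC-ad"].G)

    def test_negative_noise_rejected(self, apo_global, lags):
        with pytest.raises(ValueError):
            fd.synthesize_correlation_set(apo_global, lags, noise_sd=-1.0)


class TestTrajectoryGenerator:
    def test_determinism(self):
        cfg = fd.TrajectorySimConfig(n_trajectories=5, seed=3)
        t1 = fd.simulate_fret_trajectories(cfg)
        t2 = fd.simulate_fret_trajectories(fd.TrajectorySimConfig(
            n_trajectories=5, seed=3))
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.donor, b.donor)
            np.testing.assert_array_equal(a.acceptor, b.acceptor)

    def test_static_regime_never_changes_state(self):
        cfg = fd.TrajectorySimConfig(n_trajectories=30, regime="static", seed=1)
        for t in fd.simulate_fret_trajectories(cfg):
            assert np.unique(t.latent["states"]).size == 1

    def test_static_single_state_weights(self):
        """weights (1, 0): every bin of every trajectory comes from the
        closed-state distance distribution."""
        cfg = fd.TrajectorySimConfig(
            n_trajectories=40, regime="static", state_weights=(1.0, 0.0), seed=2
        )
        trajs = fd.simulate_fret_trajectories(cfg)
        d = np.concatenate([t.latent["distances"] for t in trajs])
        assert np.all([t.latent["state"] == 0 for t in trajs])
        assert abs(d.mean() - 0.87) < 0.05
        assert np.all(np.abs(d - 0.87) < 0.6)

    def test_fast_switching_bins_unimodal_at_weighted_mean(self):
        """Relaxation (10 ms) far below the bin width (100 ms): per-bin
        latent distances collapse onto the population-weighted mean (law of
        total expectation), with no resolved two-peak structure."""
        kin = fd.rates_from_relaxation(0.01, p_open=0.45)
        cfg = fd.TrajectorySimConfig(
            n_trajectories=40, regime="switching",
            state_weights=(kin.p_closed, kin.p_open),
            k_open=kin.k_open, k_close=kin.k_close, seed=5,
        )
        trajs = fd.simulate_fret_trajectories(cfg)
        d = np.concatenate([t.latent["distances"] for t in trajs])
        weighted_mean = 0.55 * 0.87 + 0.45 * 1.38
        assert abs(d.mean() - weighted_mean) < 3 * d.std() / np.sqrt(d.size)
        mix = fd.DistanceMixtureModel(d).fit()
        assert mix.overlapping  # a single collapsed mode, not two peaks

    def test_switching_weights_must_match_rates(self):
        with pytest.raises(ValueError, match="equilibrium"):
            fd.TrajectorySimConfig(
                n_trajectories=2, regime="switching",
                state_weights=(0.5, 0.5), k_open=2250.0, k_close=2750.0,
            )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            fd.TrajectorySimConfig(n_trajectories=2, state_weights=(0.7, 0.4))

    def test_bleach_tail_is_background(self):
        cfg = fd.TrajectorySimConfig(n_trajectories=10, seed=6,
                                     background_per_bin=2.0,
                                     post_bleach_bins=8)
        for t in fd.simulate_fret_trajectories(cfg):
            assert len(t) == t.bleach_index + 8
            tail = t.donor[t.bleach_index:] + t.acceptor[t.bleach_index:]
            assert tail.mean() < 15  # background only, far below ~500 signal

    def test_mean_length_matches_exponential(self):
        cfg = fd.TrajectorySimConfig(n_trajectories=400, seed=8,
                                     mean_length=8.8)
        trajs = fd.simulate_fret_trajectories(cfg)
        lengths = np.array([t.bleach_index for t in trajs]) * cfg.bin_width
        assert lengths.mean() == pytest.approx(8.8, rel=0.15)
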