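"""Separate and global correlation models: closed-form values, nesting,
round-trip fits, identifiability diagnostics."""

import dataclasses

import numpy as np
import pytest

import fretdyn as fd
from fretdyn.correlator import PAIRS
from fretdyn.fcsmodels import _diffusion


def _curve(pair, lags, g):
    return fd.CorrelationCurve(pair=pair, lags=lags, G=g,
                               n_samples=np.ones(lags.size, dtype=np.int64))


def _jittered(params, names, rng):
    return dataclasses.replace(
        params, **{nm: getattr(params, nm) * rng.uniform(0.5, 2.0) for nm in names}
    )


# ---------------------------------------------------------------------------
# closed-form evaluation
# ---------------------------------------------------------------------------


class TestEvalSeparate:
    def test_zero_lag_amplitude(self, apo_acd_separate):
        """G(tau -> 0+) = 1/(N (1-f)) for the triplet-corrected AC."""
        val = fd.eval_separate(1e-12, apo_acd_separate, kind="AC")
        assert val == pytest.approx(1.0 / (7.287 * (1 - 0.282)), rel=1e-6)
        assert val == pytest.approx(0.1911, abs=5e-5)

    def test_long_lag_limit(self, apo_acd_separate):
        assert fd.eval_separate(1e4, apo_acd_separate, kind="AC") < 1e-6

    def test_value_at_transit_time(self):
        """f = 0, tau = tau_D: G = (1/N) (1/2) (1 + 1/p^2)^(-1/2)."""
        p = fd.SeparateFitParams(n=4.0, tau_d=2e-4, p=5.0, f=0.0)
        expect = (1 / 4.0) * 0.5 * (1 + 1 / 25.0) ** -0.5
        assert fd.eval_separate(2e-4, p, kind="AC") == pytest.approx(expect, rel=1e-12)

    def test_cc_kind_drops_triplet(self, apo_acd_separate):
        ac = fd.eval_separate(1e-6, apo_acd_separate, kind="AC")
        cc = fd.eval_separate(1e-6, apo_acd_separate, kind="CC")
        assert ac > cc  # triplet boosts short lags

    def test_invalid_lag_rejected(self, apo_acd_separate):
        with pytest.raises(ValueError):
            fd.eval_separate(0.0, apo_acd_separate)
        with pytest.raises(ValueError):
            fd.eval_separate(-1e-6, apo_acd_separate)


class TestEvalGlobal:
    def test_dynamic_factor_at_tau_i(self, apo_global):
        """At tau = tau_I the donor-AC dynamic multiplier is
        1 + alpha e^-1 + beta = 1.1678 for the apo parameter set."""
        sep = fd.SeparateFitParams(n=apo_global.n, f=apo_global.f,
                                   tau_d=apo_global.tau_d, p=apo_global.p,
                                   tau_t=apo_global.tau_t)
        ratio = fd.eval_global(190e-6, apo_global, "AC-d") / fd.eval_separate(
            190e-6, sep, "AC"
        )
        assert ratio == pytest.approx(1 + 0.13 * np.exp(-1) + 0.12, rel=1e-9)
        assert ratio == pytest.approx(1.1678, abs=1e-4)

    def test_cc_dynamic_amplitude(self, apo_global):
        """sqrt(alpha gamma) ~ 3.6e-3 for apo alpha = 0.13, gamma ~ 1e-4."""
        assert np.sqrt(apo_global.alpha * apo_global.gamma_dyn) == pytest.approx(
            3.6e-3, abs=2e-4
        )

    def test_cc_pairs_identical(self, apo_global, lags):
        da = fd.eval_global(lags, apo_global, "CC-da")
        ad = fd.eval_global(lags, apo_global, "CC-ad")
        np.testing.assert_array_equal(da, ad)

    def test_nesting_reduces_to_separate(self, lags):
        """Zeroed dynamic/static terms and Delta = 0 collapse all four
        curves onto the separate model with shared parameters."""
        g = fd.GlobalFitParams(n=5.0, tau_d=3e-4, tau_i=1e-4, f=0.2,
                               tau_t=4e-6, p=6.0)
        sep = fd.SeparateFitParams(n=5.0, tau_d=3e-4, p=6.0, f=0.2, tau_t=4e-6)
        np.testing.assert_allclose(
            fd.eval_global(lags, g, "AC-d"), fd.eval_separate(lags, sep, "AC"),
            rtol=1e-14,
        )
        np.testing.assert_allclose(
            fd.eval_global(lags, g, "CC-da"), fd.eval_separate(lags, sep, "CC"),
            rtol=1e-14,
        )

    def test_diffusion_strictly_decreasing_and_positive(self, apo_global, lags):
        d = _diffusion(lags, apo_global.tau_d, apo_global.p)
        assert np.all(np.diff(d) < 0)
        for pair in PAIRS:
            assert np.all(fd.eval_global(lags, apo_global, pair) > 0)

    def test_unknown_pair(self, apo_global):
        with pytest.raises(ValueError, match="pair"):
            fd.eval_global(1e-5, apo_global, "AC-x")


# ---------------------------------------------------------------------------
# separate fits
# ---------------------------------------------------------------------------


class TestFitSeparate:
    def test_apo_acd_round_trip(self, apo_acd_separate, lags):
        """Noise-free synthesis -> jittered init -> recovery within 0.1%."""
        g = fd.eval_separate(lags, apo_acd_separate, "AC")
        rng = np.random.default_rng(11)
        init = _jittered(apo_acd_separate, ("n", "f", "tau_d", "tau_t"), rng)
        res = fd.fit_separate(_curve("AC-d", lags, g), init=init, seed=2)
        assert res.converged
        for nm in ("n", "f", "tau_d", "p", "tau_t"):
            assert getattr(res.params, nm) == pytest.approx(
                getattr(apo_acd_separate, nm), rel=1e-3
            ), nm

    def test_cc_round_trip(self, lags):
        truth = fd.SeparateFitParams(n=110.008, tau_d=454.090e-6, p=6.853, f=0.0)
        g = fd.eval_separate(lags, truth, "CC")
        res = fd.fit_separate(_curve("CC-da", lags, g), seed=0)
        assert res.params.n == pytest.approx(truth.n, rel=1e-3)
        assert res.params.tau_d == pytest.approx(truth.tau_d, rel=1e-3)
        assert res.params.f == 0.0  # CC fits carry no triplet term

    def test_truth_init_is_fixed_point(self, apo_acd_separate, lags):
        g = fd.eval_separate(lags, apo_acd_separate, "AC")
        res = fd.fit_separate(_curve("AC-d", lags, g), init=apo_acd_separate,
                              n_starts=0, seed=0)
        for nm in ("n", "f", "tau_d", "p", "tau_t"):
            assert getattr(res.params, nm) == pytest.approx(
                getattr(apo_acd_separate, nm), rel=1e-8
            )

    def test_fixing_reference_parameters(self, apo_acd_separate, lags):
        """p, f and tau_T can be pinned from reference measurements."""
        g = fd.eval_separate(lags, apo_acd_separate, "AC")
        res = fd.fit_separate(
            _curve("AC-d", lags, g),
            fixed={"p": 6.9, "f": 0.282, "tau_t": 3.813e-6},
            seed=0,
        )
        assert res.params.p == 6.9
        assert res.bse["p"] == 0.0
        assert res.params.tau_d == pytest.approx(208.477e-6, rel=1e-4)

    def test_degenerate_curve_rejected(self, lags):
        with pytest.raises(ValueError, match="degenerate"):
            fd.fit_separate(_curve("AC-d", lags, np.full(lags.size, 0.2)))

    def test_too_few_points_rejected(self):
        lags = np.logspace(-6, -5.5, 5)
        with pytest.raises(ValueError, match="lag points"):
            fd.fit_separate(_curve("AC-d", lags, 1.0 / (1 + lags * 1e4)))


class TestSeparateReport:
    def test_relative_columns_from_printed_values(
        self, apo_acd_separate, apo_aca_separate, lags
    ):
        """rel.N = N_ACa / N_ACd and dtau_D = tau_D,ACa - tau_D,ACd."""
        results = {}
        for pair, truth in (("AC-d", apo_acd_separate), ("AC-a", apo_aca_separate)):
            g = fd.eval_separate(lags, truth, "AC")
            results[pair] = fd.fit_separate(_curve(pair, lags, g), init=truth,
                                            seed=0)
        report = fd.build_separate_report(results)
        assert report.rel_n["AC-d"] == 1.0
        assert report.delta_tau_d["AC-d"] == 0.0
        assert round(report.rel_n["AC-a"], 3) == 6.176
        assert round(report.delta_tau_d["AC-a"] * 1e6, 3) == -16.632

    def test_single_curve_report(self, apo_acd_separate, lags):
        g = fd.eval_separate(lags, apo_acd_separate, "AC")
        res = fd.fit_separate(_curve("AC-d", lags, g), init=apo_acd_separate, seed=0)
        report = fd.build_separate_report({"AC-d": res})
        assert report.rel_n == {"AC-d": 1.0}
        assert report.delta_tau_d == {"AC-d": 0.0}

    def test_missing_reference_rejected(self, apo_aca_separate, lags):
        g = fd.eval_separate(lags, apo_aca_separate, "AC")
        res = fd.fit_separate(_curve("AC-a", lags, g), seed=0)
        with pytest.raises(ValueError, match="AC-d"):
            fd.build_separate_report({"AC-a": res})


# ---------------------------------------------------------------------------
# global fits
# ---------------------------------------------------------------------------


class TestFitGlobal:
    def test_apo_round_trip_from_jittered_inits(self, apo_global, lags):
        """Noise-free four-curve synthesis recovers every free parameter to
        well under 1% from multiplicatively jittered inits."""
        curves = fd.synthesize_correlation_set(apo_global, lags)
        rng = np.random.default_rng(5)
        init = _jittered(
            apo_global,
            ("n", "tau_d", "tau_i", "alpha", "beta_static", "gamma_dyn",
             "delta_static"),
            rng,
        )
        res = fd.fit_global(curves, init=init, seed=7)
        assert res.converged
        for nm in ("n", "tau_d", "tau_i", "alpha", "beta_static",
                   "gamma_dyn", "delta_static"):
            assert getattr(res.params, nm) == pytest.approx(
                getattr(apo_global, nm), rel=1e-2
            ), nm
        assert res.tau_i_identifiable

    def test_dpc_round_trip_tau_i_weakly_constrained(self, dpc_global, lags):
        """The lipid-locked column: tiny dynamic amplitudes leave tau_I with
        an uncertainty comparable to its (small) estimate under modest noise."""
        amp = fd.eval_global(lags[0], dpc_global, "AC-d")
        rng = np.random.default_rng(4)
        curves = {}
        weights = {}
        for pair in PAIRS:
            g = fd.eval_global(lags, dpc_global, pair)
            sd = 0.02 * np.abs(g)
            curves[pair] = _curve(pair, lags, g + rng.normal(0, sd))
            weights[pair] = 1.0 / sd
        res = fd.fit_global(curves, init=dpc_global, weights=weights, seed=4)
        assert res.converged
        assert res.params.tau_i < 5e-5          # recovered small
        assert res.bse["tau_i"] > 0.3 * res.params.tau_i

    def test_no_dynamics_flags_tau_i_unidentifiable(self, apo_global, lags):
        truth = dataclasses.replace(apo_global, alpha=0.0, gamma_dyn=0.0)
        curves = fd.synthesize_correlation_set(truth, lags)
        res = fd.fit_global(
            curves, init=dataclasses.replace(apo_global, tau_i=5e-5), seed=0
        )
        assert not res.tau_i_identifiable

    def test_noise_round_trip_tau_i(self, apo_global, lags):
        """Per-point 2% (relative) noise, inverse-sd weights: the median
        relative tau_I error over 200 seeds stays below 10%."""
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            curves, weights = {}, {}
            for pair in PAIRS:
                g = fd.eval_global(lags, apo_global, pair)
                sd = 0.02 * np.abs(g)
                curves[pair] = _curve(pair, lags, g + rng.normal(0, sd))
                weights[pair] = 1.0 / sd
            res = fd.fit_global(curves, init=apo_global, weights=weights,
                                n_starts=2, seed=seed)
            errs.append(abs(res.params.tau_i - apo_global.tau_i) / apo_global.tau_i)
        assert np.median(errs) < 0.10

    def test_missing_pair_rejected(self, apo_global, lags):
        curves = fd.synthesize_correlation_set(apo_global, lags)
        curves.pop("CC-ad")
        with pytest.raises(ValueError, match="CC-ad"):
            fd.fit_global(curves)

    def test_summary_mentions_parameters(self, apo_global, lags):
        curves = fd.synthesize_correlation_set(apo_global, lags)
        res = fd.fit_global(curves, init=apo_global, n_starts=0, seed=0)
        text = res.summary()
        for token in ("tau_i", "alpha", "converged"):
            assert token in text
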