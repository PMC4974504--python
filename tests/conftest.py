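"""Shared fixtures: reference parameter sets and small simulated streams."""

import numpy as np
import pytest

import fretdyn as fd

#: canonical quasi-log lag grid used by the synthesis round trips
LAGS = np.logspace(-6, 1, 200)


@pytest.fixture(scope="session")
def lags():
    return LAGS.copy()


@pytest.fixture(scope="session")
def apo_acd_separate():
    """Apo donor-autocorrelation separate-model parameter set."""
    return fd.SeparateFitParams(
        n=7.287, f=0.282, tau_d=208.477e-6, p=6.900, tau_t=3.813e-6
    )


@pytest.fixture(scope="session")
def apo_aca_separate():
    """Apo acceptor-autocorrelation separate-model parameter set."""
    return fd.SeparateFitParams(
        n=45.001, f=0.331, tau_d=191.845e-6, p=6.900, tau_t=8.827e-6
    )


@pytest.fixture(scope="session")
def apo_global():
    """Apo global-model parameter set (shared N, tau_D, tau_I and the
    donor/acceptor dynamic and static terms)."""
    return fd.GlobalFitParams(
        n=9.11, tau_d=220e-6, tau_i=190e-6, alpha=0.13, beta_static=0.12,
        gamma_dyn=1.01e-4, delta_static=0.25, delta_shift=-16.632e-6,
        f=0.282, tau_t=3.813e-6, p=6.9,
    )


@pytest.fixture(scope="session")
def dpc_global():
    """Lipid-saturated (locked) global parameter set: tau_I small, dynamic
    amplitudes near zero."""
    return fd.GlobalFitParams(
        n=8.87, tau_d=224e-6, tau_i=15e-6, alpha=0.04, beta_static=0.07,
        gamma_dyn=1.0e-3, delta_static=0.15, delta_shift=0.0,
        f=0.284, tau_t=3.224e-6, p=6.9,
    )


@pytest.fixture(scope="session")
def single_species_stream():
    """Short photon stream of one static species (no switching, no triplet),
    equally bright in both channels — the uncorrelated-FRET baseline for
    correlator tests."""
    cfg = fd.DiffusionSimConfig(
        n_molecules=30,
        duration=4.0,
        seed=101,
        brightness=((25_000.0, 25_000.0), (25_000.0, 25_000.0)),
        k_open=0.0,
        k_close=0.0,
        triplet_fraction=0.0,
    )
    return cfg, fd.simulate_photon_stream(cfg)


def poisson_stream(rate: float, duration: float, seed: int) -> fd.PhotonStream:
    """Two independent homogeneous Poisson channels (no correlations)."""
    rng = np.random.default_rng(seed)
    times, channels = [], []
    for ch in (0, 1):
        n = rng.poisson(rate * duration)
        times.append(rng.uniform(0, duration, n))
        channels.append(np.full(n, ch, dtype=np.uint8))
    t = np.concatenate(times)
    c = np.concatenate(channels)
    order = np.argsort(t)
    return fd.PhotonStream(times=t[order], channels=c[order], duration=duration)
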