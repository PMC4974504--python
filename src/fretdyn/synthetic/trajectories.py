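"""Binned smFRET trajectory simulation (TIRF-style, 100 ms bins).

Each trajectory is one surface-immobilized molecule observed until
single-step photobleaching (bleach time exponential, mean ~8.8 s).  Per-bin
latent dye separations (R0 units) are drawn according to the regime:

``static``
    The molecule holds one conformational state for its whole trajectory
    (state drawn from the configured weights).  Its own mean distance is
    drawn once from the state's distribution; bins scatter around it with a
    small within-state spread.  The cohort-level histogram width is the
    configured state sd (between-molecule heterogeneity plus within-state
    breathing); no molecule ever visits both peaks — the signature of a
    lipid-locked conformation.

``switching``
    A two-state Markov chain (exact exponential dwells) runs through the
    trajectory; each 100 ms bin gets the occupancy-weighted mixture of fresh
    per-state distance draws.  When the relaxation time 1/(k_open+k_close)
    is far below the bin width every bin sits near the population-weighted
    mean; when dwells are longer than bins, bins alternate between the two
    peaks and single trajectories contribute to both.

Latent distances map to efficiencies through the Forster relation, then to
donor/acceptor Poisson counts with crosstalk and gamma distortions applied
(so the downstream corrections are genuinely exercised), plus background.
Post-bleach bins contain background only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ..smfret import BinnedTrajectory

__all__ = ["TrajectorySimConfig", "simulate_fret_trajectories", "sample_telegraph"]


@dataclass
class TrajectorySimConfig:
    """Configuration of the binned-trajectory simulation.

    Distances are in R0 units with component 0 the closed (smaller-distance)
    state; times in seconds.  In the switching regime the state weights must
    equal the equilibrium populations implied by the rates (enforced;
    construct them via :mod:`fretdyn.kinetics`).
    """

    n_trajectories: int = 26
    bin_width: float = 0.1
    mean_length: float = 8.8
    regime: str = "static"
    state_distance_means: tuple = (0.87, 1.38)
    state_distance_sds: tuple = (0.08, 0.08)
    state_weights: tuple = (0.55, 0.45)
    within_state_sd: float = 0.03
    k_open: float | None = None
    k_close: float | None = None
    total_photons_per_bin_mean: float = 500.0
    crosstalk_beta: float = 0.08
    gamma_brightness: float = 1.1
    background_per_bin: float = 2.0
    post_bleach_bins: int = 10
    max_bins: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be at least 1")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if not self.mean_length > 0:
            raise ValueError("mean_length must be positive")
        if self.regime not in ("static", "switching"):
            raise ValueError(f"regime must be 'static' or 'switching', got {self.regime!r}")
        w = np.asarray(self.state_weights, dtype=float)
        if w.shape != (2,) or np.any(w < 0) or np.any(w > 1):
            raise ValueError("state_weights must be two probabilities")
        if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"state_weights must sum to 1, got {w.sum()}")
        mu = np.asarray(self.state_distance_means, dtype=float)
        sd = np.asarray(self.state_distance_sds, dtype=float)
        if mu.shape != (2,) or sd.shape != (2,) or np.any(sd <= 0) or np.any(mu <= 0):
            raise ValueError("state distance means/sds must be two positive values")
        if mu[0] >= mu[1]:
            raise ValueError("closed-state mean distance must be below the open-state one")
        if not 0 <= self.within_state_sd < min(sd):
            raise ValueError("within_state_sd must lie in [0, min(state sds))")
        if self.regime == "switching":
            if self.k_open is None or self.k_close is None:
                raise ValueError("switching regime requires k_open and k_close")
            if not (self.k_open > 0 and self.k_close > 0):
                raise ValueError("switching rates must be positive")
            ksum = self.k_open + self.k_close
            eq = (self.k_close / ksum, self.k_open / ksum)
            if not np.allclose(eq, w, atol=1e-6):
                raise ValueError(
                    f"state_weights {tuple(w)} must equal the equilibrium "
                    f"populations {eq} implied by the rates"
                )
        if not self.total_photons_per_bin_mean > 0:
            raise ValueError("total_photons_per_bin_mean must be positive")
        if not 0 <= self.crosstalk_beta < 1:
            raise ValueError("crosstalk_beta must lie in [0, 1)")
        if not self.gamma_brightness > 0:
            raise ValueError("gamma_brightness must be positive")
        if self.background_per_bin < 0:
            raise ValueError("background_per_bin must be >= 0")

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "n_trajectories", "bin_width", "mean_length", "regime",
            "within_state_sd", "k_open", "k_close",
            "total_photons_per_bin_mean", "crosstalk_beta",
            "gamma_brightness", "background_per_bin", "post_bleach_bins",
            "max_bins", "seed",
        )}
        out["state_distance_means"] = list(self.state_distance_means)
        out["state_distance_sds"] = list(self.state_distance_sds)
        out["state_weights"] = list(self.state_weights)
        return out


def sample_telegraph(k_open: float, k_close: float, duration: float, seed: int = 0,
                     start_state: int | None = None):
    """Exact two-state telegraph realisation over [0, duration].

    Returns ``(switch_times, states)``: the state ``states[i]`` (0 = closed,
    1 = open) holds from ``switch_times[i]`` to ``switch_times[i+1]`` (the
    last one to ``duration``).  ``switch_times[0]`` is 0.
    """
    if not (k_open > 0 and k_close > 0):
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    p_open = k_open / (k_open + k_close)
    s = int(rng.random() < p_open) if start_state is None else int(start_state)
    times = [0.0]
    states = [s]
    t = 0.0
    while True:
        rate = k_close if s == 1 else k_open
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        s = 1 - s
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=np.int8)


@njit(cache=False)
def _bin_occupancy(switch_times, states, n_bins, bin_width):
    """Open-state occupancy fraction of each bin from a telegraph path."""
    occ = np.zeros(n_bins)
    n_seg = switch_times.shape[0]
    for i in range(n_seg):
        t0 = switch_times[i]
        t1 = switch_times[i + 1] if i + 1 < n_seg else n_bins * bin_width
        if states[i] == 0:
            continue
        b0 = int(t0 / bin_width)
        b1 = min(int(t1 / bin_width), n_bins - 1)
        for b in range(b0, b1 + 1):
            lo = max(t0, b * bin_width)
            hi = min(t1, (b + 1) * bin_width)
            if hi > lo:
                occ[b] += (hi - lo) / bin_width
    return occ


def simulate_fret_trajectories(config: TrajectorySimConfig) -> list:
    """Generate a cohort of binned trajectories (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    mu = np.asarray(config.state_distance_means, dtype=float)
    sd = np.asarray(config.state_distance_sds, dtype=float)
    w = np.asarray(config.state_weights, dtype=float)
    sw = config.within_state_sd
    # between-molecule spread so that the marginal per-state sd stays at sd
    sd_between = np.sqrt(np.maximum(sd**2 - sw**2, 0.0))

    out = []
    for tid in range(config.n_trajectories):
        bleach_t = rng.exponential(config.mean_length)
        n_sig = int(np.clip(math.ceil(bleach_t / config.bin_width), 1, config.max_bins))
        if config.regime == "static":
            s = int(rng.random() < w[1])  # 1 = open
            centre = rng.normal(mu[s], sd_between[s])
            dists = centre + sw * rng.standard_normal(n_sig)
            latent = {"regime": "static", "state": s, "centre": centre,
                      "states": np.full(n_sig, s, dtype=np.int8)}
        else:
            sub = int(rng.integers(0, 2**31 - 1))
            switch_times, states = sample_telegraph(
                config.k_open, config.k_close, n_sig * config.bin_width, seed=sub
            )
            occ = _bin_occupancy(switch_times, states, n_sig, config.bin_width)
            d_closed = rng.normal(mu[0], sd[0], size=n_sig)
            d_open = rng.normal(mu[1], sd[1], size=n_sig)
            dists = (1.0 - occ) * d_closed + occ * d_open
            latent = {"regime": "switching", "occupancy": occ,
                      "states": (occ > 0.5).astype(np.int8)}
        dists = np.clip(dists, 1e-3, None)
        eff = 1.0 / (1.0 + dists**6)
        lam = config.total_photons_per_bin_mean
        lam_d = (1.0 - eff) * lam / config.gamma_brightness
        lam_a = eff * lam + config.crosstalk_beta * lam_d
        donor = rng.poisson(lam_d).astype(float)
        acceptor = rng.poisson(lam_a).astype(float)
        if config.background_per_bin > 0:
            donor += rng.poisson(config.background_per_bin, size=n_sig)
            acceptor += rng.poisson(config.background_per_bin, size=n_sig)
        if config.post_bleach_bins > 0:
            tail_d = rng.poisson(config.background_per_bin, size=config.post_bleach_bins)
            tail_a = rng.poisson(config.background_per_bin, size=config.post_bleach_bins)
            donor = np.concatenate([donor, tail_d.astype(float)])
            acceptor = np.concatenate([acceptor, tail_a.astype(float)])
        latent["distances"] = dists
        latent["bleach_time"] = bleach_t
        out.append(
            BinnedTrajectory(
                trajectory_id=tid,
                bin_width=config.bin_width,
                donor=donor,
                acceptor=acceptor,
                bleach_index=n_sig,
                latent=latent,
            )
        )
    return out
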