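"""Brownian-dynamics photon-stream simulation for FCS/FCCS.

Molecules diffuse in a periodic box around a 3D Gaussian detection profile

    W(r) = exp(-2 (x^2+y^2)/mu^2 - 2 z^2/z0^2),        z0 = p * mu,

while interconverting between a closed and an open FRET state at rates
k_open / k_close.  Each state has its own brightness in each detection
channel; emission is Poisson with rate brightness * W(r), gated by a
two-state triplet (bright/dark) telegraph with stationary dark fraction f
and correlation time tau_T.  Donor photons leak into the acceptor channel
with probability beta; background photons are Poisson-added per channel.
The periodic box keeps the molecule number fixed, so the correlation
amplitude relates to the profile-weighted occupancy.

Only Brownian motion is discretized (positions advance on the ``time_step``
grid; Brownian increments are exact at any step size).  Both telegraph
processes are sampled with exact exponential dwell times, and photons are
emitted from the piecewise-constant-rate segments between telegraph events
with exact uniform arrival times — so microsecond triplet kinetics are
reproduced faithfully at a multi-microsecond position step.

The box defaults to half-widths (3.5 mu, 3.5 mu, 2.2 z0): the detection
profile is below 1e-8 (lateral) / 4e-4 (axial) of its peak at the boundary,
so wrap-around re-entry is invisible in the correlations while the molecule
count stays small enough to simulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ..photons import PhotonStream

__all__ = ["DiffusionSimConfig", "simulate_photon_stream"]


@dataclass
class DiffusionSimConfig:
    """Configuration of the diffusing-molecule photon simulation.

    Times are seconds, lengths micrometres, rates 1/s, brightness photons/s.

    ``brightness[state][channel]`` gives the peak (focus-centre) emission
    rate of state ``state`` (0 = closed, 1 = open) into channel ``channel``
    (0 = donor, 1 = acceptor).  Defaults put the high-FRET closed state
    bright in the acceptor channel and the open state bright in the donor
    channel, apo-like switching rates from the measured ~200 us relaxation
    and 55/45 closed/open populations, and the reference-measurement triplet
    (f ~ 0.28, tau_T ~ 3.8 us).  The time step only discretizes diffusion
    and must stay below tau_D/10.
    """

    n_molecules: int = 40
    duration: float = 10.0
    time_step: float = 5e-6
    diffusion_coeff: float = 70.0          # um^2/s -> tau_D = mu^2/4D ~ 223 us
    focus_lateral: float = 0.25            # mu, um
    aspect_ratio: float = 3.0              # p; axial radius z0 = p * mu
    box_half_widths: tuple | None = None   # um; default (3.5 mu, 3.5 mu, 2.2 z0)
    brightness: tuple = ((10_000.0, 40_000.0), (40_000.0, 10_000.0))
    k_open: float = 2250.0
    k_close: float = 2750.0
    triplet_fraction: float = 0.28
    triplet_time: float = 3.8e-6
    crosstalk_beta: float = 0.0
    background_rate: float = 0.0           # photons/s per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be at least 1")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.time_step > 0:
            raise ValueError("time_step must be positive")
        for name in ("diffusion_coeff", "focus_lateral", "aspect_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k_open < 0 or self.k_close < 0:
            raise ValueError("switching rates must be >= 0")
        if (self.k_open > 0) != (self.k_close > 0):
            raise ValueError("switching rates must be both zero or both positive")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet_fraction must lie in [0, 1)")
        if not self.triplet_time > 0:
            raise ValueError("triplet_time must be positive")
        if not 0.0 <= self.crosstalk_beta < 1.0:
            raise ValueError("crosstalk_beta must lie in [0, 1)")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.box_half_widths is None:
            mu, z0 = self.focus_lateral, self.axial_radius
            self.box_half_widths = (3.5 * mu, 3.5 * mu, 2.2 * z0)
        if len(self.box_half_widths) != 3 or any(h <= 0 for h in self.box_half_widths):
            raise ValueError("box_half_widths must be three positive lengths")
        if self.time_step > self.tau_d / 10:
            raise ValueError(
                f"time_step {self.time_step:.3g}s too coarse: must be at most "
                f"tau_D/10 = {self.tau_d / 10:.3g}s to resolve the transit"
            )
        q = np.asarray(self.brightness, dtype=float)
        if q.shape != (2, 2) or np.any(q < 0):
            raise ValueError("brightness must be a 2x2 array of rates >= 0")
        if self.k_open + self.k_close > 0 and np.allclose(q[0], q[1]):
            raise ValueError(
                "two-state dynamics requires a brightness contrast between "
                "the states in at least one channel"
            )

    # -- derived quantities (ground truth for oracle tests) -----------------

    @property
    def axial_radius(self) -> float:
        """z0 = p * mu in micrometres."""
        return self.aspect_ratio * self.focus_lateral

    @property
    def tau_d(self) -> float:
        """Implied transit time mu^2 / (4 D) in seconds."""
        return self.focus_lateral**2 / (4.0 * self.diffusion_coeff)

    @property
    def p_open_eq(self) -> float:
        k = self.k_open + self.k_close
        return self.k_open / k if k > 0 else 0.0

    @property
    def box_volume(self) -> float:
        hx, hy, hz = self.box_half_widths
        return 8.0 * hx * hy * hz

    @property
    def effective_focus_molecules(self) -> float:
        """Mean molecule number in the effective focal volume
        V_eff = pi^(3/2) mu^2 z0 (sets the ideal correlation amplitude 1/N)."""
        v_eff = math.pi**1.5 * self.focus_lateral**2 * self.axial_radius
        return self.n_molecules * v_eff / self.box_volume

    def mean_profile_weight(self) -> float:
        """Box average of the detection profile <W> (analytic, via erf)."""
        from scipy.special import erf

        mu, z0 = self.focus_lateral, self.axial_radius
        out = 1.0
        for h, w in zip(self.box_half_widths, (mu, mu, z0)):
            out *= math.sqrt(math.pi / 2.0) * (w / (2 * h)) * erf(math.sqrt(2.0) * h / w)
        return out

    def expected_count_rate(self, channel: int) -> float:
        """Mean detected rate in a channel: profile-weighted brightness of
        both states at their equilibrium occupancy, times the triplet bright
        fraction, with crosstalk routing and background."""
        q = np.asarray(self.brightness, dtype=float)
        occ = np.array([1.0 - self.p_open_eq, self.p_open_eq])
        rate_d = float((occ * q[:, 0]).sum())
        rate_a = float((occ * q[:, 1]).sum())
        w = self.mean_profile_weight() * self.n_molecules * (1.0 - self.triplet_fraction)
        if channel == 0:
            return w * rate_d * (1.0 - self.crosstalk_beta) + self.background_rate
        return w * (rate_a + self.crosstalk_beta * rate_d) + self.background_rate

    def to_dict(self) -> dict:
        return {
            "n_molecules": self.n_molecules,
            "duration_s": self.duration,
            "time_step_s": self.time_step,
            "diffusion_coeff_um2_s": self.diffusion_coeff,
            "focus_lateral_um": self.focus_lateral,
            "aspect_ratio": self.aspect_ratio,
            "box_half_widths_um": list(self.box_half_widths),
            "brightness_cps": [list(row) for row in np.asarray(self.brightness)],
            "k_open_per_s": self.k_open,
            "k_close_per_s": self.k_close,
            "triplet_fraction": self.triplet_fraction,
            "triplet_time_s": self.triplet_time,
            "crosstalk_beta": self.crosstalk_beta,
            "background_rate_cps": self.background_rate,
            "seed": self.seed,
        }


@njit(cache=False)
def _diffusion_kernel(
    seed,
    n_steps,
    n_mol,
    dt,
    hx, hy, hz,
    sigma,
    inv_mu2, inv_z2,
    q_cd, q_ca, q_od, q_oa,   # brightness closed/open x donor/acceptor
    k_open, k_close, p_open_eq,
    k_to_dark, k_to_bright, f_dark,
    beta,
    out_d, out_a,
):
    """Brownian steps + exact telegraph/emission sampling.

    Fills ``out_d``/``out_a`` with (unsorted) photon arrival times and
    returns (n_donor, n_acceptor, open_steps, overflow) where overflow=1
    signals exhausted output capacity.
    """
    np.random.seed(seed)
    x = np.empty(n_mol)
    y = np.empty(n_mol)
    z = np.empty(n_mol)
    state = np.empty(n_mol, dtype=np.int8)       # 1 = open
    dark = np.empty(n_mol, dtype=np.int8)
    t_switch = np.empty(n_mol)                   # next conformational flip
    t_triplet = np.empty(n_mol)                  # next triplet transition
    inf = 1.0e30
    switching = k_open + k_close > 0.0
    for m in range(n_mol):
        x[m] = (2.0 * np.random.random() - 1.0) * hx
        y[m] = (2.0 * np.random.random() - 1.0) * hy
        z[m] = (2.0 * np.random.random() - 1.0) * hz
        state[m] = 1 if np.random.random() < p_open_eq else 0
        if switching:
            rate = k_close if state[m] == 1 else k_open
            t_switch[m] = np.random.exponential(1.0 / rate)
        else:
            t_switch[m] = inf
        if f_dark > 0.0:
            dark[m] = 1 if np.random.random() < f_dark else 0
            rate = k_to_bright if dark[m] == 1 else k_to_dark
            t_triplet[m] = np.random.exponential(1.0 / rate)
        else:
            dark[m] = 0
            t_triplet[m] = inf

    cap_d = out_d.shape[0]
    cap_a = out_a.shape[0]
    nd = 0
    na = 0
    open_steps = 0
    # profile cutoff: beyond arg > 7 the expected emission per step is
    # < brightness * dt * 8e-7 photons — negligible
    cutoff = 7.0
    # normals buffer, refilled in blocks
    block = 1024
    need = 3 * n_mol
    buf = np.random.standard_normal(block * need)
    bpos = 0
    for s in range(n_steps):
        if bpos + need > buf.shape[0]:
            buf = np.random.standard_normal(block * need)
            bpos = 0
        t_end = (s + 1) * dt
        for m in range(n_mol):
            xm = x[m] + sigma * buf[bpos]
            ym = y[m] + sigma * buf[bpos + 1]
            zm = z[m] + sigma * buf[bpos + 2]
            bpos += 3
            if xm > hx:
                xm -= 2.0 * hx
            elif xm < -hx:
                xm += 2.0 * hx
            if ym > hy:
                ym -= 2.0 * hy
            elif ym < -hy:
                ym += 2.0 * hy
            if zm > hz:
                zm -= 2.0 * hz
            elif zm < -hz:
                zm += 2.0 * hz
            x[m] = xm
            y[m] = ym
            z[m] = zm
            if state[m] == 1:
                open_steps += 1
            arg = (xm * xm + ym * ym) * inv_mu2 + zm * zm * inv_z2
            if arg > cutoff:
                # out of focus: just advance the telegraph clocks
                while t_switch[m] <= t_end:
                    state[m] = 1 - state[m]
                    rate = k_close if state[m] == 1 else k_open
                    t_switch[m] += np.random.exponential(1.0 / rate)
                while t_triplet[m] <= t_end:
                    dark[m] = 1 - dark[m]
                    rate = k_to_bright if dark[m] == 1 else k_to_dark
                    t_triplet[m] += np.random.exponential(1.0 / rate)
                continue
            w = np.exp(-2.0 * arg)
            # walk the piecewise-constant segments inside this step
            t0 = t_end - dt
            while True:
                t_next = t_end
                if t_switch[m] < t_next:
                    t_next = t_switch[m]
                if t_triplet[m] < t_next:
                    t_next = t_triplet[m]
                seg = t_next - t0
                if seg > 0.0 and dark[m] == 0:
                    if state[m] == 1:
                        qd = q_od
                        qa = q_oa
                    else:
                        qd = q_cd
                        qa = q_ca
                    kd = np.random.poisson(qd * w * seg) if qd > 0.0 else 0
                    ka = np.random.poisson(qa * w * seg) if qa > 0.0 else 0
                    for _ in range(kd):
                        tt = t0 + np.random.random() * seg
                        if beta > 0.0 and np.random.random() < beta:
                            if na < cap_a:
                                out_a[na] = tt
                                na += 1
                            else:
                                return nd, na, open_steps, 1
                        else:
                            if nd < cap_d:
                                out_d[nd] = tt
                                nd += 1
                            else:
                                return nd, na, open_steps, 1
                    for _ in range(ka):
                        if na < cap_a:
                            out_a[na] = t0 + np.random.random() * seg
                            na += 1
                        else:
                            return nd, na, open_steps, 1
                if t_next >= t_end:
                    break
                if t_switch[m] <= t_triplet[m]:
                    state[m] = 1 - state[m]
                    rate = k_close if state[m] == 1 else k_open
                    t_switch[m] += np.random.exponential(1.0 / rate)
                else:
                    dark[m] = 1 - dark[m]
                    rate = k_to_bright if dark[m] == 1 else k_to_dark
                    t_triplet[m] += np.random.exponential(1.0 / rate)
                t0 = t_next
    return nd, na, open_steps, 0


def simulate_photon_stream(config: DiffusionSimConfig) -> PhotonStream:
    """Run the Brownian/two-state photon simulation.

    Returns a :class:`~fretdyn.photons.PhotonStream` whose metadata echoes
    the configuration and records the latent open-state occupancy fraction
    (diagnostic; never used by fitting code).  Deterministic given
    ``config.seed``.
    """
    n_steps = int(round(config.duration / config.time_step))
    if n_steps < 10:
        raise ValueError("duration must span at least 10 time steps")
    q = np.asarray(config.brightness, dtype=float)
    f = config.triplet_fraction
    # stationary dark fraction f and correlation time tau_T imply
    # k(bright->dark) = f/tau_T and k(dark->bright) = (1-f)/tau_T
    k_to_dark = f / config.triplet_time
    k_to_bright = (1.0 - f) / config.triplet_time
    sigma = math.sqrt(2.0 * config.diffusion_coeff * config.time_step)
    hx, hy, hz = config.box_half_widths

    expected = (
        config.expected_count_rate(0) + config.expected_count_rate(1)
    ) * config.duration
    cap = int(3 * expected) + 100_000
    out_d = np.empty(cap, dtype=np.float64)
    out_a = np.empty(cap, dtype=np.float64)

    nd, na, open_steps, overflow = _diffusion_kernel(
        config.seed & 0x7FFFFFFF,
        n_steps,
        config.n_molecules,
        config.time_step,
        hx, hy, hz,
        sigma,
        1.0 / config.focus_lateral**2,
        1.0 / config.axial_radius**2,
        q[0, 0], q[0, 1], q[1, 0], q[1, 1],
        config.k_open, config.k_close, config.p_open_eq,
        k_to_dark, k_to_bright, f,
        config.crosstalk_beta,
        out_d, out_a,
    )
    if overflow:
        raise RuntimeError(
            "photon capacity exceeded (simulated rate far above the "
            "configured expectation); check the brightness configuration"
        )
    times_d = out_d[:nd]
    times_a = out_a[:na]
    rng = np.random.default_rng((config.seed, 0xB0))
    if config.background_rate > 0:
        n_bg = rng.poisson(config.background_rate * config.duration, size=2)
        times_d = np.concatenate([times_d, rng.uniform(0, config.duration, n_bg[0])])
        times_a = np.concatenate([times_a, rng.uniform(0, config.duration, n_bg[1])])
    times = np.concatenate([times_d, times_a])
    channels = np.concatenate(
        [
            np.zeros(times_d.size, dtype=np.uint8),
            np.ones(times_a.size, dtype=np.uint8),
        ]
    )
    order = np.argsort(times, kind="stable")
    times = np.clip(times[order], 0.0, config.duration)
    metadata = {
        "config": config.to_dict(),
        "seed": config.seed,
        "latent": {
            "open_fraction": open_steps / (n_steps * config.n_molecules),
            "tau_d_s": config.tau_d,
            "effective_focus_molecules": config.effective_focus_molecules,
        },
    }
    return PhotonStream(
        times=times,
        channels=channels[order],
        duration=config.duration,
        resolution=config.time_step,
        metadata=metadata,
    )
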