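"""Corrected smFRET efficiencies, distance distributions and state classification.

Binned donor/acceptor intensity trajectories of surface-immobilized molecules
are converted to corrected FRET efficiencies,

    I_A^corr = I_A - beta * I_D           (donor -> acceptor crosstalk)
    E        = I_A^corr / (I_A^corr + gamma * I_D),

where beta is the donor emission fraction leaking into the acceptor channel
and gamma = (phi_A eta_A)/(phi_D eta_D) corrects the relative brightness of
the two dyes.  Efficiencies map to dye separations through the Forster
relation E = 1/(1 + (R/R0)^6); distances are handled in R0 units throughout
and converted to Angstrom via the Forster radius only at I/O.

The pooled distance distribution of a two-state protein is decomposed into
two Gaussian components by a least-squares fit to the histogram (the standard
figure workflow); a sample-level EM fit is provided as a cross-check.  Each
trajectory is then classified by which component(s) its bins visit — a
molecule switching during the observation contributes to both peaks, a
static molecule to exactly one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedTrajectory",
    "FretCorrections",
    "GaussianPair",
    "TrajectoryClass",
    "DistanceMixtureModel",
    "DistanceMixtureResults",
    "compute_efficiency",
    "efficiency_to_distance",
    "distance_to_efficiency",
    "detect_bleach",
    "fit_two_gaussians",
    "fit_two_gaussians_em",
    "classify_trajectory",
    "trajectory_distances",
    "analyze_cohort",
    "write_trajectories_csv",
    "read_trajectories_csv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BinnedTrajectory:
    """Binned two-channel intensity trace of one immobilized molecule.

    ``bleach_index`` is the first post-bleach bin; bins from there on are
    excluded from analysis.  ``latent`` may carry generator ground truth
    (states, distances) for oracle tests; analysis code never reads it.
    """

    trajectory_id: int
    bin_width: float
    donor: np.ndarray
    acceptor: np.ndarray
    bleach_index: int | None = None
    latent: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor traces must have equal length")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if self.bleach_index is not None and not 0 <= self.bleach_index <= len(self):
            raise ValueError("bleach_index out of range")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def n_analysis_bins(self) -> int:
        return len(self) if self.bleach_index is None else self.bleach_index

    def analysis_slice(self) -> slice:
        return slice(0, self.n_analysis_bins)


@dataclass(frozen=True)
class FretCorrections:
    """Crosstalk/brightness corrections and the Forster radius (Angstrom)."""

    beta_crosstalk: float = 0.0
    gamma_brightness: float = 1.0
    r0: float = 51.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_crosstalk < 1.0:
            raise ValueError("beta_crosstalk must lie in [0, 1)")
        if not self.gamma_brightness > 0:
            raise ValueError("gamma_brightness must be positive")
        if not self.r0 > 0:
            raise ValueError("r0 must be positive")


@dataclass
class GaussianPair:
    """Two-component Gaussian mixture in ascending-mean order.

    Component 0 is the smaller-distance ("closed") state, component 1 the
    larger-distance ("open") state; distances are in R0 units.
    """

    weights: tuple
    means: tuple
    sds: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        if not (w.shape == mu.shape == sd.shape == (2,)):
            raise ValueError("GaussianPair needs exactly two components")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        if np.any(w < 0) or np.any(sd <= 0) or not np.all(np.isfinite(mu)):
            raise ValueError("invalid mixture parameters")
        if mu[0] > mu[1]:  # enforce ascending-mean convention
            order = np.argsort(mu)
            w, mu, sd = w[order], mu[order], sd[order]
        object.__setattr__(self, "weights", tuple(w))
        object.__setattr__(self, "means", tuple(mu))
        object.__setattr__(self, "sds", tuple(sd))

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, mu, sd in zip(self.weights, self.means, self.sds):
            out += w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        return out

    def posterior(self, x) -> np.ndarray:
        """Posterior component probabilities, shape (n, 2)."""
        x = np.asarray(x, dtype=float)
        comp = np.empty((x.size, 2))
        for j, (w, mu, sd) in enumerate(zip(self.weights, self.means, self.sds)):
            comp[:, j] = w * np.exp(-0.5 * ((x.ravel() - mu) / sd) ** 2) / sd
        total = comp.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return comp / total

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "means_R0": list(self.means),
            "sds_R0": list(self.sds),
        }


@dataclass(frozen=True)
class TrajectoryClass:
    """Per-trajectory state-occupancy label with per-peak bin counts."""

    label: str  # closed_only | open_only | both | unclassified
    n_closed: int
    n_open: int

    def __post_init__(self) -> None:
        if self.label not in ("closed_only", "open_only", "both", "unclassified"):
            raise ValueError(f"unknown label {self.label!r}")


# ---------------------------------------------------------------------------
# efficiency / distance
# ---------------------------------------------------------------------------


def compute_efficiency(traj: BinnedTrajectory, corr: FretCorrections) -> np.ndarray:
    """Corrected FRET efficiency per pre-bleach bin.

    Bins where both corrected intensities vanish carry no signal and are
    dropped (logged).  Returned efficiencies lie in [0, 1].
    """
    sl = traj.analysis_slice()
    i_d = traj.donor[sl]
    i_a = traj.acceptor[sl]
    i_a_corr = np.clip(i_a - corr.beta_crosstalk * i_d, 0.0, None)
    denom = i_a_corr + corr.gamma_brightness * i_d
    good = denom > 0
    if not good.all():
        logger.info(
            "trajectory %s: dropped %d empty bin(s)",
            traj.trajectory_id,
            int((~good).sum()),
        )
    return i_a_corr[good] / denom[good]


def efficiency_to_distance(e, r0: float = 1.0):
    """Distance from FRET efficiency, R = R0 (1/E - 1)^(1/6).

    E = 0 or 1 are out of the invertible domain and map to inf / 0 with a
    warning; E outside [0, 1] raises.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0) or np.any(e_arr > 1):
        raise ValueError("efficiency must lie in [0, 1]")
    if np.any(e_arr == 0) or np.any(e_arr == 1):
        warnings.warn(
            "efficiency of exactly 0 or 1 is out of domain; returning inf/0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        out = r0 * (1.0 / e_arr - 1.0) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


def distance_to_efficiency(r, r0: float = 1.0):
    """FRET efficiency from distance, E = 1/(1 + (R/R0)^6)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("distance must be non-negative")
    out = 1.0 / (1.0 + (r_arr / r0) ** 6)
    return out if out.ndim else float(out)


def trajectory_distances(traj: BinnedTrajectory, corr: FretCorrections,
                         r0_units: bool = True) -> np.ndarray:
    """Per-bin distances of one trajectory (R0 units by default).

    Bins with out-of-domain efficiency (0 or 1, i.e. no signal in one
    channel) are dropped.
    """
    e = compute_efficiency(traj, corr)
    e = e[(e > 0) & (e < 1)]
    r0 = 1.0 if r0_units else corr.r0
    return efficiency_to_distance(e, r0)


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------


def detect_bleach(traj: BinnedTrajectory, drop_sigma: float = 5.0,
                  tail_fraction: float = 0.35) -> int | None:
    """Single-step photobleach change point on the total intensity trace.

    A candidate step is a one-bin drop larger than ``drop_sigma`` times the
    robust (MAD) scale of the bin-to-bin differences.  The trace bleaches if,
    after its last candidate step, the mean intensity has fallen below
    ``tail_fraction`` of the pre-step level (i.e. the drop is sustained to
    the trace end, at background).  The returned index is the first candidate
    step — for a two-step trace (acceptor then donor bleach) analysis must
    stop at the first event.
    """
    if len(traj) < 5:
        raise ValueError("bleach detection needs at least 5 bins")
    total = traj.donor + traj.acceptor
    diffs = np.diff(total)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    scale = 1.4826 * mad if mad > 0 else max(np.std(diffs), 1.0)
    candidates = np.nonzero(-diffs > drop_sigma * scale)[0] + 1
    if candidates.size == 0:
        return None
    last = candidates[-1]
    if last >= len(traj):
        return None
    before = float(np.mean(total[:last]))
    after = float(np.mean(total[last:]))
    if before <= 0 or after > tail_fraction * before:
        return None
    return int(candidates[0])


# ---------------------------------------------------------------------------
# two-Gaussian decomposition
# ---------------------------------------------------------------------------


class DistanceMixtureModel:
    """Two-Gaussian decomposition of a pooled distance distribution.

    The samples are histogrammed on a fixed grid and the density is fit by
    bounded least squares with w N(mu1, s1) + (1-w) N(mu2, s2), matching the
    histogram-fitting workflow of smFRET figures (an EM fit on the raw
    samples is available via :func:`fit_two_gaussians_em` as a cross-check).

    Parameters
    ----------
    distances : array
        Pooled per-bin distances in R0 units (>= 100 samples).
    bin_width : float
        Histogram bin width in R0 units.
    sd_max : float
        Upper bound on the component widths (R0 units).  A component much
        broader than the state peaks is an envelope fit sweeping up the
        other state's mass, not a conformational state — peaks wider than
        ~0.15 R0 could not be resolved as two states at the separations this
        analysis deals with anyway.
    """

    def __init__(self, distances, bin_width: float = 0.025, sd_max: float = 0.15):
        d = np.asarray(distances, dtype=float)
        d = d[np.isfinite(d)]
        if d.size < 100:
            raise ValueError(f"need >= 100 samples, got {d.size}")
        if not bin_width > 0:
            raise ValueError("bin_width must be positive")
        if not sd_max > 0:
            raise ValueError("sd_max must be positive")
        self.distances = d
        self.bin_width = bin_width
        self.sd_max = sd_max
        lo = np.floor(d.min() / bin_width) * bin_width - bin_width
        hi = np.ceil(d.max() / bin_width) * bin_width + bin_width
        self.edges = np.arange(lo, hi + bin_width / 2, bin_width)
        self.density, _ = np.histogram(d, bins=self.edges, density=True)
        self.centers = 0.5 * (self.edges[:-1] + self.edges[1:])

    def _default_starts(self) -> list:
        """Diverse quantile-pair inits: a minor component hiding in either
        tail is found from the (2, 98) / (10, 90) pairs even when the
        central quantiles sit inside one clump."""
        d = self.distances
        spread = max(float(np.std(d)) / 2, self.bin_width)
        starts = []
        for qlo, qhi, w in ((25, 75, 0.5), (10, 90, 0.5), (2, 98, 0.5),
                            (2, 98, 0.85), (2, 98, 0.15)):
            mlo, mhi = np.quantile(d, [qlo / 100, qhi / 100])
            if mhi - mlo < self.bin_width:
                mhi = mlo + self.bin_width
            starts.append(np.array([w, mlo, mhi, spread, spread]))
        return starts

    def fit(self, init: GaussianPair | None = None, n_starts: int = 3,
            seed: int = 0) -> "DistanceMixtureResults":
        d = self.distances
        lo = np.array([0.0, d.min() - 1.0, d.min() - 1.0, 1e-4, 1e-4])
        hi = np.array([1.0, d.max() + 1.0, d.max() + 1.0, self.sd_max,
                       self.sd_max])
        if init is not None:
            x0 = np.array([init.weights[0], *init.means, *init.sds])
            base_starts = [x0]
        else:
            base_starts = self._default_starts()
            x0 = base_starts[0]

        def unpack(x) -> GaussianPair:
            w1, mu1, mu2, s1, s2 = x
            # keep component identity during optimization; reorder at the end
            w = np.array([w1, 1 - w1])
            comp = GaussianPair.__new__(GaussianPair)
            object.__setattr__(comp, "weights", tuple(w))
            object.__setattr__(comp, "means", (mu1, mu2))
            object.__setattr__(comp, "sds", (s1, s2))
            return comp

        def residual(x):
            return unpack(x).pdf(self.centers) - self.density

        rng = np.random.default_rng(seed)
        best = None
        starts = list(base_starts)
        for _ in range(n_starts - 1):
            jit = x0 * rng.uniform(0.8, 1.25, size=5)
            jit[0] = np.clip(x0[0] + rng.uniform(-0.2, 0.2), 0.05, 0.95)
            starts.append(np.clip(jit, lo, hi))
        for start in starts:
            res = least_squares(residual, np.clip(start, lo, hi),
                                bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
        w1, mu1, mu2, s1, s2 = best.x
        pair = GaussianPair(weights=(w1, 1 - w1), means=(mu1, mu2), sds=(s1, s2))
        sep = abs(mu2 - mu1)
        overlap = sep < 2.0 * max(s1, s2)
        if overlap:
            logger.info("mixture components unresolved (|mu2-mu1| < 2 max sd)")
        return DistanceMixtureResults(
            pair=pair,
            ssr=2 * best.cost,
            converged=bool(best.status > 0),
            overlapping=bool(overlap),
            n_samples=d.size,
            model=self,
        )


def write_trajectories_csv(trajectories, path, sidecar_config: dict | None = None):
    """Write a cohort to CSV (trajectory_id, bin_index, I_D, I_A) with an
    optional JSON config sidecar next to it (same stem, .json)."""
    import json
    from pathlib import Path

    import pandas as pd

    rows = []
    for t in trajectories:
        for i in range(len(t)):
            rows.append((t.trajectory_id, i, t.donor[i], t.acceptor[i],
                         t.bleach_index if t.bleach_index is not None else -1,
                         t.bin_width))
    pd.DataFrame(
        rows, columns=["trajectory_id", "bin_index", "I_D", "I_A",
                       "bleach_index", "bin_width_s"]
    ).to_csv(path, index=False)
    if sidecar_config is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps(sidecar_config, indent=2, sort_keys=True)
        )


def read_trajectories_csv(path) -> list:
    """Read a cohort written by :func:`write_trajectories_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("bin_index")
        bleach = int(grp["bleach_index"].iloc[0]) if "bleach_index" in grp else -1
        out.append(
            BinnedTrajectory(
                trajectory_id=int(tid),
                bin_width=float(grp["bin_width_s"].iloc[0])
                if "bin_width_s" in grp
                else 0.1,
                donor=grp["I_D"].to_numpy(dtype=float),
                acceptor=grp["I_A"].to_numpy(dtype=float),
                bleach_index=None if bleach < 0 else bleach,
            )
        )
    return out


@dataclass
class DistanceMixtureResults:
    """Fitted two-Gaussian decomposition with diagnostics."""

    pair: GaussianPair
    ssr: float
    converged: bool
    overlapping: bool
    n_samples: int
    model: DistanceMixtureModel | None = None

    @property
    def closed_fraction(self) -> float:
        """Weight of the smaller-distance (closed) component."""
        return self.pair.weights[0]

    def summary(self) -> str:
        p = self.pair
        return (
            "DistanceMixtureResults\n"
            f"  samples: {self.n_samples}   SSR: {self.ssr:.4g}   "
            f"converged: {self.converged}   overlapping: {self.overlapping}\n"
            f"  closed: w={p.weights[0]:.3f}  mu={p.means[0]:.3f} R0  "
            f"sd={p.sds[0]:.3f} R0\n"
            f"  open:   w={p.weights[1]:.3f}  mu={p.means[1]:.3f} R0  "
            f"sd={p.sds[1]:.3f} R0"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        if m is not None:
            ax.bar(m.centers, m.density, width=m.bin_width, alpha=0.4,
                   label="histogram")
            x = np.linspace(m.edges[0], m.edges[-1], 400)
        else:
            x = np.linspace(0, 2, 400)
        ax.plot(x, self.pair.pdf(x), "g-", label="two-Gaussian fit")
        ax.set_xlabel("distance (R0 units)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def fit_two_gaussians(distances, bin_width: float = 0.025,
                      init: GaussianPair | None = None, **kw) -> GaussianPair:
    """Histogram-based two-Gaussian fit; functional wrapper returning the pair."""
    return DistanceMixtureModel(distances, bin_width=bin_width).fit(init=init, **kw).pair


def fit_two_gaussians_em(distances, seed: int = 0) -> GaussianPair:
    """Sample-level EM fit (scikit-learn GaussianMixture) as a cross-check
    against the histogram least-squares decomposition."""
    from sklearn.mixture import GaussianMixture

    d = np.asarray(distances, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, covariance_type="diag",
                         n_init=3, random_state=seed).fit(d)
    return GaussianPair(
        weights=tuple(gm.weights_),
        means=tuple(gm.means_.ravel()),
        sds=tuple(np.sqrt(gm.covariances_.ravel())),
    )


# ---------------------------------------------------------------------------
# per-trajectory classification
# ---------------------------------------------------------------------------


def classify_trajectory(
    distances,
    pair: GaussianPair,
    min_bins: int = 3,
    min_posterior: float = 0.8,
    min_separation_frac: float = 0.5,
) -> TrajectoryClass:
    """Classify one trajectory by which mixture component(s) its bins visit.

    A bin counts as a confident visit to a component when its posterior
    probability under the fitted pair exceeds ``min_posterior`` (bins near
    the component boundary stay ambiguous and count toward neither).  The
    label is "both" iff each component collects at least ``min_bins``
    confident visits *and* the two visited groups are genuinely bimodal:
    their mean distances must differ by at least ``min_separation_frac``
    times the component separation (a static molecule whose own distance
    happens to straddle the decision boundary scatters bins narrowly around
    one value and fails this, whereas a switching molecule puts bins at both
    component means).  Otherwise the majority side wins, with ties broken
    toward the closed (smaller-distance) component (logged).  Trajectories
    shorter than ``min_bins`` are unclassified.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < min_bins:
        return TrajectoryClass("unclassified", 0, 0)
    post = pair.posterior(d)
    closed_mask = post[:, 0] >= min_posterior
    open_mask = post[:, 1] >= min_posterior
    n_closed = int(closed_mask.sum())
    n_open = int(open_mask.sum())
    if n_closed >= min_bins and n_open >= min_bins:
        group_sep = float(d[open_mask].mean() - d[closed_mask].mean())
        if group_sep >= min_separation_frac * (pair.means[1] - pair.means[0]):
            return TrajectoryClass("both", n_closed, n_open)
    if n_closed == n_open:
        logger.info("classification tie (%d bins each); assigning closed", n_closed)
        return TrajectoryClass("closed_only", n_closed, n_open)
    label = "closed_only" if n_closed > n_open else "open_only"
    return TrajectoryClass(label, n_closed, n_open)


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------


def analyze_cohort(
    trajectories,
    corrections: FretCorrections,
    bin_width: float = 0.025,
    min_bins: int = 3,
    min_posterior: float = 0.8,
) -> dict:
    """Full smFRET distribution analysis of a trajectory cohort.

    Pools per-bin distances over all trajectories, fits the two-Gaussian
    decomposition, classifies every trajectory, and returns a result bundle:
    the mixture results, per-trajectory classes, the label tally, and the
    closed-state population (mixture closed-component weight, percent).
    """
    per_traj = [trajectory_distances(t, corrections) for t in trajectories]
    pooled = np.concatenate([d for d in per_traj if d.size]) if per_traj else np.empty(0)
    mix = DistanceMixtureModel(pooled, bin_width=bin_width).fit()
    classes = [
        classify_trajectory(d, mix.pair, min_bins=min_bins,
                            min_posterior=min_posterior)
        for d in per_traj
    ]
    tally = {lbl: 0 for lbl in ("closed_only", "open_only", "both", "unclassified")}
    for c in classes:
        tally[c.label] += 1
    return {
        "mixture": mix,
        "pair": mix.pair,
        "classes": classes,
        "tally": tally,
        "closed_population_pct": 100.0 * mix.closed_fraction,
        "n_trajectories": len(list(trajectories)),
        "n_bins_pooled": int(pooled.size),
    }
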