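"""Normalized auto- and cross-correlation of photon time tags.

The estimator throughout is the fluctuation correlation

    G(tau) = <dI_a(t) dI_b(t+tau)> / (<I_a><I_b>)
           = <I_a(t) I_b(t+tau)> / (<I_a><I_b>) - 1,

which decays to 0 for uncorrelated signals.  The means in the denominator are
taken over the same (lag-shifted) windows as the numerator ("symmetric
normalization"), which removes the leading finite-duration bias.

Two estimators are provided: a multi-tau correlator with quasi-logarithmic
lag coverage from the base resolution up to seconds (the workhorse), and a
brute-force direct correlator at arbitrary lags (quadratic cost, used as an
oracle on short streams).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .photons import ACCEPTOR, DONOR, PhotonStream

__all__ = [
    "PAIRS",
    "AC_PAIRS",
    "CC_PAIRS",
    "CorrelationCurve",
    "multitau_correlate",
    "direct_correlate",
    "smooth_curve",
    "write_curves_csv",
    "read_curves_csv",
]

AC_PAIRS = ("AC-d", "AC-a")
CC_PAIRS = ("CC-da", "CC-ad")
PAIRS = AC_PAIRS + CC_PAIRS

#: channel pair (a, b) correlated for each label: G_ab(tau) = <a(t) b(t+tau)>
_PAIR_CHANNELS = {
    "AC-d": (DONOR, DONOR),
    "AC-a": (ACCEPTOR, ACCEPTOR),
    "CC-da": (DONOR, ACCEPTOR),
    "CC-ad": (ACCEPTOR, DONOR),
}


@dataclass
class CorrelationCurve:
    """One correlation function on a (quasi-log) lag grid.

    ``n_samples`` is the number of products averaged at each lag, used for
    weighting in fits and in curve smoothing.
    """

    pair: str
    lags: np.ndarray
    G: np.ndarray
    n_samples: np.ndarray
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.pair not in PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}; expected one of {PAIRS}")
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.n_samples = np.asarray(self.n_samples)
        if not (self.lags.shape == self.G.shape == self.n_samples.shape):
            raise ValueError("lags, G and n_samples must have equal length")
        if self.lags.size:
            if np.any(self.lags <= 0):
                raise ValueError("lags must be strictly positive")
            if np.any(np.diff(self.lags) <= 0):
                raise ValueError("lags must be strictly increasing")
            if not np.all(np.isfinite(self.G)):
                raise ValueError("correlation values must be finite")
            if np.any(self.n_samples <= 0):
                raise ValueError("n_samples must be positive")

    def __len__(self) -> int:
        return self.lags.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pair": self.pair,
                "lag_s": self.lags,
                "G": self.G,
                "n_samples": self.n_samples,
            }
        )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def _binned_counts(stream: PhotonStream, channel: int, resolution: float) -> np.ndarray:
    """Counts per whole bin of width ``resolution``; a trailing partial bin
    (and its photons) is dropped so estimates at coarser resolutions remain
    consistent with pairwise-coarsened fine bins."""
    times = stream.channel_times(channel)
    if times.size == 0:
        raise ValueError(
            f"stream has no photons in the "
            f"{'donor' if channel == DONOR else 'acceptor'} channel"
        )
    n_bins = max(int(stream.duration / resolution), 1)
    idx = (times / resolution).astype(np.int64)
    idx = idx[idx < n_bins]
    return np.bincount(idx, minlength=n_bins).astype(np.float32)


# ---------------------------------------------------------------------------
# multi-tau
# ---------------------------------------------------------------------------


@njit(cache=False)
def _corr_at_lag(a, b, n, k):
    """Symmetrically normalized correlation of a[0:n] with b[k:n+k]... at
    integer lag k over n-valid samples; returns (G, n_samples)."""
    m = n - k
    if m < 2:
        return np.nan, 0
    sab = 0.0
    sa = 0.0
    sb = 0.0
    for i in range(m):
        sab += a[i] * b[i + k]
        sa += a[i]
        sb += b[i + k]
    if sa == 0.0 or sb == 0.0:
        return np.nan, m
    return m * sab / (sa * sb) - 1.0, m


@njit(cache=False)
def _multitau_kernel(a, b, m_lags, n_levels, max_k_total):
    """Multi-tau scheme: level 0 correlates at lags 1..m; every subsequent
    level halves the time resolution (pairwise bin sum) and correlates at
    lags m/2+1..m in coarsened units.  ``max_k_total`` caps the lag in base
    bins (duration guard).  Returns (lag in base bins, G, n_samples)."""
    half = m_lags // 2
    total = m_lags + (n_levels - 1) * half
    lag_out = np.empty(total, dtype=np.float64)
    g_out = np.empty(total, dtype=np.float64)
    ns_out = np.empty(total, dtype=np.int64)
    n = a.shape[0]
    out = 0
    scale = 1  # base bins per current bin
    for level in range(n_levels):
        if level == 0:
            k_lo, k_hi = 1, m_lags
        else:
            k_lo, k_hi = half + 1, m_lags
        for k in range(k_lo, k_hi + 1):
            if k * scale > max_k_total or k >= n - 1:
                return lag_out[:out], g_out[:out], ns_out[:out]
            g, m = _corr_at_lag(a, b, n, k)
            if m >= 2 and not np.isnan(g):
                lag_out[out] = k * scale
                g_out[out] = g
                ns_out[out] = m
                out += 1
        # coarsen by 2 (in place on the leading halves)
        n2 = n // 2
        if n2 < m_lags + 2:
            break
        for i in range(n2):
            a[i] = a[2 * i] + a[2 * i + 1]
            b[i] = b[2 * i] + b[2 * i + 1]
        n = n2
        scale *= 2
    return lag_out[:out], g_out[:out], ns_out[:out]


def multitau_correlate(
    stream: PhotonStream,
    pair: str,
    points_per_level: int = 16,
    n_levels: int = 20,
    base_resolution: float = 1e-6,
) -> CorrelationCurve:
    """Multi-tau correlation of a photon stream for one channel pair.

    Photons are binned at ``base_resolution``; the hierarchical scheme then
    covers lags from one base bin up to ``points_per_level * 2**(n_levels-1)``
    base bins with ``points_per_level`` lags per level (defaults span
    1 us to ~8 s).  Lags beyond a quarter of the stream duration are
    truncated with a warning, since their estimates carry too few samples.
    """
    if pair not in _PAIR_CHANNELS:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    if points_per_level < 2 or points_per_level % 2:
        raise ValueError("points_per_level must be an even integer >= 2")
    cha, chb = _PAIR_CHANNELS[pair]
    a = _binned_counts(stream, cha, base_resolution)
    b = a.copy() if chb == cha else _binned_counts(stream, chb, base_resolution)

    max_lag_bins = points_per_level * 2 ** (n_levels - 1)
    guard = int(stream.duration / 4 / base_resolution)
    if max_lag_bins > guard:
        warnings.warn(
            f"lag range exceeds duration/4; truncating lags to "
            f"{guard * base_resolution:.3g} s",
            stacklevel=2,
        )
    lag_bins, g, ns = _multitau_kernel(
        a, b, points_per_level, n_levels, min(max_lag_bins, guard)
    )
    return CorrelationCurve(
        pair=pair,
        lags=lag_bins * base_resolution,
        G=g,
        n_samples=ns,
        duration=stream.duration,
    )


# ---------------------------------------------------------------------------
# brute force
# ---------------------------------------------------------------------------


def direct_correlate(
    stream: PhotonStream,
    pair: str,
    lags,
    base_resolution: float = 1e-6,
    max_bins: int = 1_000_000,
) -> CorrelationCurve:
    """Exact binned-intensity correlation at the requested lags (seconds).

    Quadratic-cost oracle; refuses streams longer than ``max_bins`` bins at
    the base resolution.  Lags are rounded to whole base bins.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        return CorrelationCurve(
            pair=pair,
            lags=np.empty(0),
            G=np.empty(0),
            n_samples=np.empty(0, dtype=np.int64),
            duration=stream.duration,
        )
    if pair not in _PAIR_CHANNELS:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    n_bins = int(np.ceil(stream.duration / base_resolution))
    if n_bins > max_bins:
        raise ValueError(
            f"stream spans {n_bins} bins at {base_resolution:.3g} s resolution, "
            f"exceeding the {max_bins} direct-correlation guard"
        )
    cha, chb = _PAIR_CHANNELS[pair]
    a = _binned_counts(stream, cha, base_resolution).astype(np.float64)
    b = a if chb == cha else _binned_counts(stream, chb, base_resolution).astype(np.float64)

    ks = np.maximum(np.rint(lags / base_resolution).astype(np.int64), 1)
    out_lag, out_g, out_ns = [], [], []
    for k_req, lag in zip(ks, lags):
        m = a.size - k_req
        if m < 2:
            continue
        aa, bb = a[:m], b[k_req:]
        sa, sb = aa.sum(), bb.sum()
        if sa == 0 or sb == 0:
            continue
        out_lag.append(k_req * base_resolution)
        out_g.append(m * float(aa @ bb) / (sa * sb) - 1.0)
        out_ns.append(m)
    # collapse duplicate lags produced by rounding
    lag_arr = np.asarray(out_lag)
    keep = np.concatenate(([True], np.diff(lag_arr) > 0)) if lag_arr.size else []
    return CorrelationCurve(
        pair=pair,
        lags=lag_arr[keep] if lag_arr.size else np.empty(0),
        G=np.asarray(out_g)[keep] if lag_arr.size else np.empty(0),
        n_samples=np.asarray(out_ns, dtype=np.int64)[keep]
        if lag_arr.size
        else np.empty(0, dtype=np.int64),
        duration=stream.duration,
    )


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_curve(curve: CorrelationCurve, factor: int) -> CorrelationCurve:
    """Average ``factor`` adjacent lags, weighting by n_samples.

    Combined lags are geometric means of the group (natural on a log-lag
    axis); a trailing partial group is kept.  ``factor=1`` is the identity.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    if factor > len(curve):
        raise ValueError(
            f"factor {factor} exceeds the curve length {len(curve)}"
        )
    if factor == 1:
        return CorrelationCurve(
            curve.pair, curve.lags.copy(), curve.G.copy(),
            curve.n_samples.copy(), curve.duration,
        )
    lags, g, ns = [], [], []
    w_all = curve.n_samples.astype(float)
    for start in range(0, len(curve), factor):
        sl = slice(start, start + factor)
        w = w_all[sl]
        lags.append(np.exp(np.average(np.log(curve.lags[sl]), weights=w)))
        g.append(np.average(curve.G[sl], weights=w))
        ns.append(int(w.sum()))
    return CorrelationCurve(
        curve.pair, np.asarray(lags), np.asarray(g),
        np.asarray(ns, dtype=np.int64), curve.duration,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_curves_csv(curves, path) -> None:
    """Write one or more curves to CSV (columns pair, lag_s, G, n_samples)."""
    import pandas as pd

    if isinstance(curves, CorrelationCurve):
        curves = [curves]
    if isinstance(curves, dict):
        curves = list(curves.values())
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, index=False
    )


def read_curves_csv(path) -> dict:
    """Read curves from CSV into a dict pair -> CorrelationCurve.

    Tolerant of extra columns; only pair, lag_s, G (and optionally
    n_samples) are used.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"pair", "lag_s", "G"}
    if not required <= set(df.columns):
        raise ValueError(f"curve CSV must contain columns {sorted(required)}")
    out = {}
    for pair, grp in df.groupby("pair", sort=False):
        grp = grp.sort_values("lag_s")
        ns = (
            grp["n_samples"].to_numpy()
            if "n_samples" in grp.columns
            else np.ones(len(grp), dtype=np.int64)
        )
        out[str(pair)] = CorrelationCurve(
            pair=str(pair),
            lags=grp["lag_s"].to_numpy(dtype=float),
            G=grp["G"].to_numpy(dtype=float),
            n_samples=ns,
        )
    return out
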