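"""Closed-form FCS/FCCS correlation models and their least-squares fits.

Two model families are implemented, mirroring the two stages of a FRET-FCCS
analysis of a two-state protein:

**Separate (per-curve) model.**  Each auto- or cross-correlation curve is fit
independently with the standard 3D-Gaussian diffusion model times a triplet
blinking term,

    G(tau) = (1/N) * T(tau) * D(tau),
    T(tau) = 1 + f/(1-f) * exp(-tau/tau_T),
    D(tau) = (1 + tau/tau_D)^-1 * (1 + tau/(p^2 tau_D))^-1/2,

with N the mean number of molecules in the focus, tau_D the transit
(diffusion) time, p the axial/lateral focus aspect ratio, and (f, tau_T) the
triplet dark-state amplitude and time.  Cross-correlations carry no triplet
term (f = 0): triplet blinking of a single dye does not cross-correlate
between spectrally separated channels.

**Global (four-curve) model.**  The donor/acceptor autocorrelations (AC-d,
AC-a) and the two cross-correlations (CC-da, CC-ad) are fit simultaneously
with shared amplitude N, shared transit time tau_D and a shared
intramolecular dynamics time tau_I.  FRET-state interconversion at relaxation
time tau_I raises each autocorrelation and produces an anticorrelated dip in
the cross-correlations:

    AC-d : (1/N) T(tau) D(tau; tau_D)        * (1 + alpha * exp(-tau/tau_I) + beta)
    AC-a : (1/N) T(tau) D(tau; tau_D+Delta)  * (1 + gamma * exp(-tau/tau_I) + delta)
    CC   : (1/N)        D(tau; tau_D)        * (1 - sqrt(alpha*gamma) * exp(-tau/tau_I)
                                                  - sqrt(beta*delta))

alpha and gamma scale the dynamic term in the donor and acceptor channel;
beta and delta are static contributions from FRET heterogeneity that
interchanges much more slowly than the transit time (constant over the lag
window).  By the same anticorrelation algebra that gives the cross-correlation
dynamic amplitude -sqrt(alpha*gamma), the static heterogeneity enters the
cross-correlations as -sqrt(beta*delta); this symmetric form is also what
makes the shared amplitude N identifiable from the four curves (see
docs/methods.md).  Delta is a fixed transit-time correction for the acceptor
channel, taken from the separate fits.

All times are seconds internally; reporting helpers convert to microseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .correlator import AC_PAIRS, CC_PAIRS, PAIRS, CorrelationCurve

__all__ = [
    "SeparateFitParams",
    "GlobalFitParams",
    "SeparateCorrelationModel",
    "GlobalCorrelationModel",
    "SeparateFitResults",
    "GlobalFitResults",
    "SeparateFitReport",
    "eval_separate",
    "eval_global",
    "fit_separate",
    "fit_global",
    "build_separate_report",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeparateFitParams:
    """Parameters of the per-curve diffusion+triplet model (times in seconds)."""

    n: float            # mean molecules in focus
    tau_d: float        # transit time (s)
    p: float            # axial/lateral aspect ratio of the focus
    f: float = 0.0      # triplet amplitude, in [0, 1)
    tau_t: float = 4e-6  # triplet time constant (s)

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not self.tau_d > 0:
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")
        if not self.p > 0:
            raise ValueError(f"p must be positive, got {self.p}")
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"f must lie in [0, 1), got {self.f}")
        if not self.tau_t > 0:
            raise ValueError(f"tau_t must be positive, got {self.tau_t}")

    def to_dict(self, microseconds: bool = False) -> dict:
        scale = 1e6 if microseconds else 1.0
        suffix = "us" if microseconds else "s"
        return {
            "N": self.n,
            "f": self.f,
            f"tau_D_{suffix}": self.tau_d * scale,
            "p": self.p,
            f"tau_T_{suffix}": self.tau_t * scale,
        }


@dataclass(frozen=True)
class GlobalFitParams:
    """Parameters of the shared four-curve model (times in seconds).

    ``delta_shift`` is the fixed transit-time correction Delta applied to the
    acceptor autocorrelation (may be negative).  ``f``, ``tau_t`` and ``p``
    are predefined from reference measurements / separate fits.
    """

    n: float
    tau_d: float
    tau_i: float
    alpha: float = 0.0          # dynamic-term scale, donor AC
    beta_static: float = 0.0    # static FRET contribution, donor AC
    gamma_dyn: float = 0.0      # dynamic-term scale, acceptor AC
    delta_static: float = 0.0   # static FRET contribution, acceptor AC
    delta_shift: float = 0.0    # transit-time correction for AC-a (s)
    f: float = 0.0
    tau_t: float = 4e-6
    p: float = 6.9

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")
        for name in ("tau_d", "tau_i", "tau_t", "p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("alpha", "beta_static", "gamma_dyn", "delta_static"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"f must lie in [0, 1), got {self.f}")
        if self.tau_d + self.delta_shift <= 0:
            raise ValueError("tau_d + delta_shift must remain positive")

    def to_dict(self, microseconds: bool = False) -> dict:
        scale = 1e6 if microseconds else 1.0
        suffix = "us" if microseconds else "s"
        return {
            "N": self.n,
            f"tau_D_{suffix}": self.tau_d * scale,
            f"tau_i_{suffix}": self.tau_i * scale,
            "alpha": self.alpha,
            "beta": self.beta_static,
            "gamma": self.gamma_dyn,
            "delta": self.delta_static,
            f"Delta_{suffix}": self.delta_shift * scale,
            "f": self.f,
            f"tau_T_{suffix}": self.tau_t * scale,
            "p": self.p,
        }


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def _diffusion(tau: np.ndarray, tau_d: float, p: float) -> np.ndarray:
    return 1.0 / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (p * p * tau_d))


def _triplet(tau: np.ndarray, f: float, tau_t: float) -> np.ndarray:
    if f == 0.0:
        return np.ones_like(tau)
    return 1.0 + (f / (1.0 - f)) * np.exp(-tau / tau_t)


def _check_lags(lag) -> np.ndarray:
    tau = np.asarray(lag, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lags must be strictly positive")
    return tau


def eval_separate(lag, params: SeparateFitParams, kind: str = "AC"):
    """Evaluate the per-curve diffusion(+triplet) model at lag(s) in seconds.

    ``kind`` is "AC" (triplet included) or "CC" (triplet amplitude forced to
    zero).  Returns a scalar for scalar input.
    """
    tau = _check_lags(lag)
    if kind not in ("AC", "CC"):
        raise ValueError(f"kind must be 'AC' or 'CC', got {kind!r}")
    f = params.f if kind == "AC" else 0.0
    out = (1.0 / params.n) * _triplet(tau, f, params.tau_t) * _diffusion(
        tau, params.tau_d, params.p
    )
    return out if out.ndim else float(out)


def eval_global(lag, params: GlobalFitParams, pair: str):
    """Evaluate the shared four-curve model for one pair at lag(s) in seconds."""
    tau = _check_lags(lag)
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}; expected one of {sorted(PAIRS)}")
    dyn = np.exp(-tau / params.tau_i)
    if pair == "AC-d":
        out = (
            (1.0 / params.n)
            * _triplet(tau, params.f, params.tau_t)
            * _diffusion(tau, params.tau_d, params.p)
            * (1.0 + params.alpha * dyn + params.beta_static)
        )
    elif pair == "AC-a":
        out = (
            (1.0 / params.n)
            * _triplet(tau, params.f, params.tau_t)
            * _diffusion(tau, params.tau_d + params.delta_shift, params.p)
            * (1.0 + params.gamma_dyn * dyn + params.delta_static)
        )
    else:  # CC-da and CC-ad are identical by model symmetry
        amp_dyn = math.sqrt(params.alpha * params.gamma_dyn)
        amp_static = math.sqrt(params.beta_static * params.delta_static)
        out = (
            (1.0 / params.n)
            * _diffusion(tau, params.tau_d, params.p)
            * (1.0 - amp_dyn * dyn - amp_static)
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------


def _multistart_least_squares(residual, x0, lower, upper, n_starts, seed, rng_jitter=(0.5, 2.0)):
    """Trust-region-reflective least squares from the given init plus
    ``n_starts`` multiplicatively jittered inits; returns the best-cost result.

    Multi-start guards against basin exchange among the model's time
    constants (tau_I / tau_T / tau_D can swap roles from a bad init).
    """
    rng = np.random.default_rng(seed)
    x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
    starts = [x0]
    for _ in range(n_starts):
        jitter = rng.uniform(rng_jitter[0], rng_jitter[1], size=x0.size)
        starts.append(np.clip(x0 * jitter, lower, upper))
    best = None
    for start in starts:
        # strictly inside the bounds for TRF
        start = np.minimum(np.maximum(start, lower + 1e-300), upper)
        try:
            res = least_squares(
                residual,
                start,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=20000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    return best


def _standard_errors(jac: np.ndarray, ssr: float, n_points: int, n_free: int) -> np.ndarray:
    """Asymptotic standard errors from the Jacobian at the optimum.

    Uses the pseudo-inverse of J^T J; directions the data do not constrain
    (singular values below tolerance) get infinite errors rather than
    spuriously small ones.
    """
    dof = max(n_points - n_free, 1)
    s2 = ssr / dof
    u, s, _ = np.linalg.svd(jac, full_matrices=False)
    tol = max(jac.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    errs = np.full(jac.shape[1], np.inf)
    good = s > tol
    if good.any():
        vt = np.linalg.svd(jac, full_matrices=False)[2]
        cov = (vt[good].T / s[good] ** 2) @ vt[good]
        diag = np.diag(cov)
        errs = np.sqrt(np.clip(diag * s2, 0.0, np.inf))
        errs[diag < 0] = np.inf
        # unconstrained directions: mark parameters dominated by null space
        if not good.all():
            null = vt[~good]
            touched = (np.abs(null) > 1e-8).any(axis=0)
            errs[touched] = np.inf
    return errs


class _FitResultsBase:
    """Common behaviour of fit results: errors, convergence, summary table."""

    _time_params: tuple = ()

    def __init__(self, params, bse: dict, ssr: float, converged: bool,
                 nfev: int, bounds: dict, n_points: int):
        self.params = params
        self.bse = bse
        self.ssr = ssr
        self.converged = converged
        self.nfev = nfev
        self.bounds = bounds
        self.n_points = n_points

    def summary(self) -> str:
        rows = []
        for name, value in self._param_items():
            err = self.bse.get(name, float("nan"))
            unit = ""
            if name in self._time_params:
                value, err, unit = value * 1e6, err * 1e6, "us"
            rows.append(f"{name:>12s}  {value:14.6g}  {err:12.4g}  {unit}")
        head = (
            f"{type(self).__name__}\n"
            f"  points: {self.n_points}   SSR: {self.ssr:.6g}   "
            f"converged: {self.converged}   nfev: {self.nfev}\n"
            f"{'parameter':>12s}  {'estimate':>14s}  {'std err':>12s}\n"
        )
        return head + "\n".join(rows)

    def _param_items(self):
        return [(f.name, getattr(self.params, f.name)) for f in fields(self.params)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.summary()


class SeparateFitResults(_FitResultsBase):
    """Results of a per-curve separate-model fit."""

    _time_params = ("tau_d", "tau_t")

    def __init__(self, *args, pair: str | None = None, kind: str = "AC", **kw):
        super().__init__(*args, **kw)
        self.pair = pair
        self.kind = kind

    def predict(self, lags) -> np.ndarray:
        return eval_separate(lags, self.params, kind=self.kind)


class GlobalFitResults(_FitResultsBase):
    """Results of the shared four-curve global fit."""

    _time_params = ("tau_d", "tau_i", "tau_t", "delta_shift")

    @property
    def tau_i_identifiable(self) -> bool:
        """False when the dynamics time constant is not constrained by the
        data (standard error exceeding the estimate, e.g. vanishing dynamic
        amplitudes)."""
        err = self.bse.get("tau_i", np.inf)
        return bool(np.isfinite(err) and err < self.params.tau_i)

    def predict(self, lags, pair: str) -> np.ndarray:
        return eval_global(lags, self.params, pair)

    def plot(self, curves: Mapping[str, CorrelationCurve] | None = None, ax=None):
        """Diagnostic overlay of data and fitted curves on a log-lag axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"AC-d": "g", "AC-a": "r", "CC-da": "k", "CC-ad": "b"}
        for pair, color in colors.items():
            if curves and pair in curves:
                c = curves[pair]
                ax.semilogx(c.lags, c.G, ".", color=color, ms=2, alpha=0.4)
                lags = c.lags
            else:
                lags = np.logspace(-6, 0, 200)
            ax.semilogx(lags, self.predict(lags, pair), "-", color=color, label=pair)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("G")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# separate model
# ---------------------------------------------------------------------------

_SEP_NAMES = ("n", "tau_d", "p", "f", "tau_t")


class SeparateCorrelationModel:
    """Per-curve diffusion(+triplet) model bound to one correlation curve.

    Parameters
    ----------
    curve : CorrelationCurve
        The measured (or synthesized) curve.  Cross-correlation pairs are fit
        without a triplet term.
    kind : str, optional
        Override the AC/CC choice inferred from ``curve.pair``.
    """

    def __init__(self, curve: CorrelationCurve, kind: str | None = None):
        if kind is None:
            kind = "AC" if curve.pair in AC_PAIRS else "CC"
        if kind not in ("AC", "CC"):
            raise ValueError(f"kind must be 'AC' or 'CC', got {kind!r}")
        if curve.lags.size < 10 or curve.lags[-1] / curve.lags[0] < 100:
            raise ValueError(
                "separate fit needs >= 10 lag points spanning >= 2 decades"
            )
        if np.ptp(curve.G) == 0:
            raise ValueError("degenerate curve: correlation values are constant")
        self.curve = curve
        self.kind = kind

    # -- defaults -----------------------------------------------------------
    def _default_init(self) -> SeparateFitParams:
        g = self.curve.G
        lags = self.curve.lags
        g0 = max(float(np.max(g[: max(3, g.size // 20)])), 1e-6)
        n0 = 1.0 / g0
        half = g0 / 2.0
        below = np.nonzero(g < half)[0]
        tau_d0 = float(lags[below[0]]) if below.size else float(np.median(lags))
        if self.kind == "AC":
            return SeparateFitParams(n=n0, tau_d=tau_d0, p=5.0, f=0.15, tau_t=4e-6)
        return SeparateFitParams(n=n0, tau_d=tau_d0, p=5.0, f=0.0, tau_t=4e-6)

    def fit(
        self,
        init: SeparateFitParams | None = None,
        bounds: Mapping[str, tuple] | None = None,
        fix: Mapping[str, float] | Iterable[str] | None = None,
        weights: np.ndarray | None = None,
        n_starts: int = 5,
        seed: int = 0,
    ) -> SeparateFitResults:
        """Bounded least squares; ``fix`` holds parameters at given values
        (mapping) or at their init values (iterable of names), supporting the
        reference-measurement workflow of fixing p, f and tau_T."""
        init = init or self._default_init()
        fixed: dict[str, float] = {}
        if fix:
            if isinstance(fix, Mapping):
                fixed = dict(fix)
            else:
                fixed = {name: getattr(init, name) for name in fix}
        if self.kind == "CC":
            fixed.setdefault("f", 0.0)
        init = replace(init, **fixed)

        lo = {"n": 1e-3, "tau_d": 1e-7, "p": 1.0, "f": 0.0, "tau_t": 1e-7}
        hi = {"n": 1e6, "tau_d": 1.0, "p": 50.0, "f": 0.999, "tau_t": 1e-3}
        if bounds:
            for k, (a, b) in bounds.items():
                lo[k], hi[k] = a, b

        free = [nm for nm in _SEP_NAMES if nm not in fixed]
        x0 = np.array([getattr(init, nm) for nm in free])
        lower = np.array([lo[nm] for nm in free])
        upper = np.array([hi[nm] for nm in free])

        g = self.curve.G
        lags = self.curve.lags
        w = np.ones_like(g) if weights is None else np.asarray(weights, float)

        def to_params(x) -> SeparateFitParams:
            kw = dict(fixed)
            kw.update({nm: v for nm, v in zip(free, x)})
            for nm in _SEP_NAMES:
                kw.setdefault(nm, getattr(init, nm))
            return SeparateFitParams(**kw)

        def residual(x):
            return w * (eval_separate(lags, to_params(x), kind=self.kind) - g)

        res = _multistart_least_squares(residual, x0, lower, upper, n_starts, seed)
        params = to_params(res.x)
        errs = _standard_errors(res.jac, 2 * res.cost, g.size, len(free))
        bse = {nm: float(e) for nm, e in zip(free, errs)}
        for nm in fixed:
            bse[nm] = 0.0
        return SeparateFitResults(
            params,
            bse,
            ssr=2 * res.cost,
            converged=bool(res.status > 0),
            nfev=res.nfev,
            bounds={nm: (lo[nm], hi[nm]) for nm in free},
            n_points=g.size,
            pair=self.curve.pair,
            kind=self.kind,
        )


def fit_separate(curve, init=None, bounds=None, fixed=None, **kw) -> SeparateFitResults:
    """Functional wrapper around :class:`SeparateCorrelationModel`."""
    return SeparateCorrelationModel(curve).fit(init=init, bounds=bounds, fix=fixed, **kw)


# ---------------------------------------------------------------------------
# the Table-style separate report
# ---------------------------------------------------------------------------


@dataclass
class SeparateFitReport:
    """Per-pair separate fits plus the derived columns rel.N and Delta tau_D.

    ``rel_n[x] = N_x / N_ACd`` and ``delta_tau_d[x] = tau_D,x - tau_D,ACd``,
    referencing everything to the donor autocorrelation.
    """

    results: dict = field(default_factory=dict)
    rel_n: dict = field(default_factory=dict)
    delta_tau_d: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for pair, res in self.results.items():
            p = res.params
            rows.append(
                {
                    "pair": pair,
                    "N": p.n,
                    "f": p.f if res.kind == "AC" else None,
                    "tau_D_us": p.tau_d * 1e6,
                    "p": p.p,
                    "tau_T_us": p.tau_t * 1e6 if res.kind == "AC" else None,
                    "rel_N": self.rel_n[pair],
                    "delta_tau_D_us": self.delta_tau_d[pair] * 1e6,
                }
            )
        return pd.DataFrame(rows).set_index("pair")

    def to_dict(self) -> dict:
        out = {}
        for pair, res in self.results.items():
            row = res.params.to_dict(microseconds=True)
            if res.kind == "CC":
                row.pop("f", None)
                row.pop("tau_T_us", None)
            row["rel_N"] = self.rel_n[pair]
            row["delta_tau_D_us"] = self.delta_tau_d[pair] * 1e6
            out[pair] = row
        return out


def build_separate_report(results: Mapping[str, SeparateFitResults]) -> SeparateFitReport:
    """Assemble the rel.N / Delta tau_D report from per-pair fit results.

    The donor autocorrelation is the reference row and must be present.
    """
    if "AC-d" not in results:
        raise ValueError("report requires an 'AC-d' result as reference")
    ref = results["AC-d"].params
    report = SeparateFitReport(results=dict(results))
    for pair, res in results.items():
        report.rel_n[pair] = res.params.n / ref.n
        report.delta_tau_d[pair] = res.params.tau_d - ref.tau_d
    return report


# ---------------------------------------------------------------------------
# global model
# ---------------------------------------------------------------------------

_GLO_NAMES = (
    "n", "tau_d", "tau_i", "alpha", "beta_static", "gamma_dyn",
    "delta_static", "delta_shift", "f", "tau_t", "p",
)
# predefined from reference measurements / separate fits unless freed
_GLO_DEFAULT_FIXED = ("delta_shift", "f", "tau_t", "p")


class GlobalCorrelationModel:
    """Shared-parameter model bound to all four correlation curves.

    Parameters
    ----------
    curves : mapping
        Pair label ("AC-d", "AC-a", "CC-da", "CC-ad") -> CorrelationCurve.
        All four pairs are required and must have overlapping lag ranges.
    """

    def __init__(self, curves: Mapping[str, CorrelationCurve]):
        missing = [p for p in PAIRS if p not in curves]
        if missing:
            raise ValueError(f"missing correlation pair(s): {missing}")
        lo = max(c.lags[0] for c in curves.values())
        hi = min(c.lags[-1] for c in curves.values())
        if not lo < hi:
            raise ValueError("curves have no overlapping lag range")
        self.curves = {p: curves[p] for p in PAIRS}

    def _default_init(self) -> GlobalFitParams:
        acd = self.curves["AC-d"]
        g0 = max(float(np.max(acd.G[: max(3, acd.G.size // 20)])), 1e-6)
        half = np.nonzero(acd.G < g0 / 2)[0]
        tau_d0 = float(acd.lags[half[0]]) if half.size else float(np.median(acd.lags))
        return GlobalFitParams(
            n=1.0 / g0, tau_d=tau_d0, tau_i=max(tau_d0 / 2, 2e-6),
            alpha=0.1, beta_static=0.1, gamma_dyn=0.01, delta_static=0.1,
        )

    def fit(
        self,
        init: GlobalFitParams | None = None,
        bounds: Mapping[str, tuple] | None = None,
        fix: Mapping[str, float] | Iterable[str] | None = None,
        weights: Mapping[str, np.ndarray] | None = None,
        n_starts: int = 5,
        seed: int = 0,
    ) -> GlobalFitResults:
        """Simultaneous bounded least squares over the concatenated residuals.

        By default ``delta_shift``, ``f``, ``tau_t`` and ``p`` are fixed at
        their init values (predefined from the separate fits / reference
        measurements); pass ``fix`` to override.  Default per-point weights
        are sqrt(n_samples) (i.e. sigma ~ 1/sqrt(averaging count)),
        normalized per curve; unit weights when curves carry no averaging
        counts.
        """
        init = init or self._default_init()
        if fix is None:
            fixed = {nm: getattr(init, nm) for nm in _GLO_DEFAULT_FIXED}
        elif isinstance(fix, Mapping):
            fixed = dict(fix)
        else:
            fixed = {nm: getattr(init, nm) for nm in fix}
        init = replace(init, **fixed)

        lo = {
            "n": 1e-3, "tau_d": 1e-6, "tau_i": 1e-6, "alpha": 0.0,
            "beta_static": 0.0, "gamma_dyn": 0.0, "delta_static": 0.0,
            "delta_shift": -1e-2, "f": 0.0, "tau_t": 1e-7, "p": 1.0,
        }
        hi = {
            "n": 1e6, "tau_d": 1e-1, "tau_i": 1e-2, "alpha": 1.0,
            "beta_static": 1.0, "gamma_dyn": 1.0, "delta_static": 1.0,
            "delta_shift": 1e-2, "f": 0.999, "tau_t": 1e-3, "p": 50.0,
        }
        if bounds:
            for k, (a, b) in bounds.items():
                lo[k], hi[k] = a, b

        free = [nm for nm in _GLO_NAMES if nm not in fixed]
        x0 = np.array([getattr(init, nm) for nm in free])
        lower = np.array([lo[nm] for nm in free])
        upper = np.array([hi[nm] for nm in free])

        pair_w = {}
        for pair, c in self.curves.items():
            if weights is not None and pair in weights:
                w = np.asarray(weights[pair], float)
            elif np.all(c.n_samples <= 1):
                w = np.ones(c.lags.size)
            else:
                w = np.sqrt(c.n_samples.astype(float))
                w /= w.mean()
            pair_w[pair] = w

        def to_params(x) -> GlobalFitParams:
            kw = dict(fixed)
            kw.update({nm: v for nm, v in zip(free, x)})
            for nm in _GLO_NAMES:
                kw.setdefault(nm, getattr(init, nm))
            return GlobalFitParams(**kw)

        def residual(x):
            try:
                params = to_params(x)
            except ValueError:
                return np.full(sum(c.lags.size for c in self.curves.values()), 1e6)
            return np.concatenate(
                [
                    pair_w[pair] * (eval_global(c.lags, params, pair) - c.G)
                    for pair, c in self.curves.items()
                ]
            )

        res = _multistart_least_squares(residual, x0, lower, upper, n_starts, seed)
        params = to_params(res.x)
        n_points = sum(c.lags.size for c in self.curves.values())
        errs = _standard_errors(res.jac, 2 * res.cost, n_points, len(free))
        # a parameter the curves carry (almost) no gradient for is
        # unidentifiable regardless of the residual level (e.g. tau_i when
        # the fitted dynamic amplitudes vanish)
        col_norms = np.linalg.norm(res.jac, axis=0)
        scale = np.abs(res.x) + 1e-300
        dead = col_norms * scale < 1e-8 * np.max(col_norms * scale)
        errs[dead] = np.inf
        bse = {nm: float(e) for nm, e in zip(free, errs)}
        for nm in fixed:
            bse[nm] = 0.0
        return GlobalFitResults(
            params,
            bse,
            ssr=2 * res.cost,
            converged=bool(res.status > 0),
            nfev=res.nfev,
            bounds={nm: (lo[nm], hi[nm]) for nm in free},
            n_points=n_points,
        )


def fit_global(curves, init=None, bounds=None, weights=None, **kw) -> GlobalFitResults:
    """Functional wrapper around :class:`GlobalCorrelationModel`."""
    return GlobalCorrelationModel(curves).fit(
        init=init, bounds=bounds, weights=weights, **kw
    )
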