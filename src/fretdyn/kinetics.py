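"""Two-state conformational kinetics.

A molecule interconverting between a closed and an open conformation,

    closed  --k_open-->  open
    open    --k_close--> closed,

relaxes toward equilibrium as a single exponential with relaxation time
``tau_r = 1/(k_open + k_close)``; the equilibrium occupancies are
``P_open = k_open/(k_open + k_close)`` and ``P_closed = 1 - P_open``.

The relaxation time is what a FRET-FCCS global fit measures (the fitted
intramolecular time constant ``tau_I``), while the occupancies are what the
smFRET population histogram measures.  This module converts between the two
experimental observables and the underlying rate constants, in both
directions, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TwoStateKinetics", "rates_from_relaxation", "kinetics_from_rates"]


@dataclass(frozen=True)
class TwoStateKinetics:
    """Rate constants and the equilibrium/relaxation quantities they imply.

    Attributes
    ----------
    k_open : float
        Closed -> open rate constant (1/s).
    k_close : float
        Open -> closed rate constant (1/s).
    """

    k_open: float
    k_close: float

    def __post_init__(self) -> None:
        if not (self.k_open > 0 and self.k_close > 0):
            raise ValueError(
                f"rate constants must be positive, got k_open={self.k_open}, "
                f"k_close={self.k_close}"
            )

    @property
    def p_open(self) -> float:
        """Equilibrium open-state occupancy."""
        return self.k_open / (self.k_open + self.k_close)

    @property
    def p_closed(self) -> float:
        """Equilibrium closed-state occupancy."""
        return self.k_close / (self.k_open + self.k_close)

    @property
    def tau_r(self) -> float:
        """Relaxation time 1/(k_open + k_close) in seconds."""
        return 1.0 / (self.k_open + self.k_close)

    def to_dict(self) -> dict:
        return {
            "k_open_per_s": self.k_open,
            "k_close_per_s": self.k_close,
            "p_open": self.p_open,
            "p_closed": self.p_closed,
            "tau_r_s": self.tau_r,
        }


def rates_from_relaxation(tau_r: float, p_open: float) -> TwoStateKinetics:
    """Rate constants from a relaxation time and the open-state occupancy.

    Inverts ``tau_r = 1/(k_open+k_close)`` and ``P_open = k_open*tau_r``:
    ``k_open = P_open/tau_r`` and ``k_close = (1-P_open)/tau_r``.

    Parameters
    ----------
    tau_r : float
        Relaxation time in seconds (e.g. the fitted FCCS ``tau_I``).
    p_open : float
        Equilibrium open fraction, strictly inside (0, 1) (e.g. the open-peak
        weight of the smFRET histogram).
    """
    if not tau_r > 0:
        raise ValueError(f"tau_r must be positive, got {tau_r}")
    if not 0.0 < p_open < 1.0:
        raise ValueError(f"p_open must lie strictly in (0, 1), got {p_open}")
    return TwoStateKinetics(k_open=p_open / tau_r, k_close=(1.0 - p_open) / tau_r)


def kinetics_from_rates(k_open: float, k_close: float) -> TwoStateKinetics:
    """Convenience constructor from the two rate constants (1/s)."""
    return TwoStateKinetics(k_open=k_open, k_close=k_close)
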