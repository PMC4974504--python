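"""Synthesis of correlation-curve sets from the global model.

The inverse of the global fit: evaluate the shared four-curve model on a lag
grid and optionally add i.i.d. Gaussian noise, producing the standard
round-trip inputs for fit validation.  CC-da and CC-ad are identical before
noise (model symmetry) but receive independent noise draws.
"""

from __future__ import annotations

import numpy as np

from ..correlator import PAIRS, CorrelationCurve
from ..fcsmodels import GlobalFitParams, eval_global

__all__ = ["synthesize_correlation_set"]


def synthesize_correlation_set(
    params: GlobalFitParams,
    lags,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Evaluate the global model for all four pairs on ``lags`` (seconds).

    ``noise_sd`` is the per-point standard deviation of additive Gaussian
    noise (0 gives the exact model evaluation).  Returns a dict
    pair -> :class:`~fretdyn.correlator.CorrelationCurve`.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0 or np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be positive, sorted and non-empty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    out = {}
    for pair in PAIRS:
        g = eval_global(lags, params, pair)
        if noise_sd > 0:
            g = g + rng.normal(0.0, noise_sd, size=lags.size)
        out[pair] = CorrelationCurve(
            pair=pair,
            lags=lags.copy(),
            G=np.asarray(g, dtype=float),
            n_samples=np.ones(lags.size, dtype=np.int64),
        )
    return out
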