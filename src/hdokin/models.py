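"""Closed-form kinetic models.

Two models cover all time-course fitting in the workflow:

* the single-exponential approach to a plateau,
  ``P(t) = A0 - A exp(-k t)``, used for product-formation time courses under
  single-turnover conditions; and
* the two-channel rise / common decay transient,
  ``A(t) = A0 + dA * k1/(k2-k1) * (exp(-k1 t) - exp(-k2 t))
         + dA2 * k1p/(k2-k1p) * (exp(-k1p t) - exp(-k2 t))``,
  describing the biphasic formation and monophasic decay of an optically
  detected intermediate in stopped-flow traces.  Each rise channel is the
  Bateman intermediate of a sequential first-order pair sharing the decay
  constant ``k2``.

When a formation constant approaches the decay constant the Bateman
expression degenerates; within a relative tolerance the analytic limit
``dA * k * t * exp(-k t)`` is evaluated instead, so the model is continuous
in its rate constants and never divides by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

#: relative |k2 - ki| / ki below which the degenerate Bateman limit is used
DEGENERATE_RTOL = 1e-6


@dataclass(frozen=True)
class SingleExpParams:
    """Parameters of the exponential-approach model (amounts in µM, k in min^-1)."""

    a0: float  # plateau amplitude
    a: float   # approach amplitude
    k: float   # rate constant, > 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k <= 0:
            raise InputError("rate constant k must be finite and > 0")


@dataclass(frozen=True)
class RiseDecayParams:
    """Parameters of the biphasic-rise / monophasic-decay transient model.

    Amplitudes in absorbance units; rate constants in the unit of the time
    axis they are fitted on (s^-1 for stopped-flow traces).  By reporting
    convention ``k1 >= k1p`` (the first channel is the faster riser).
    """

    a0: float   # baseline absorbance
    da: float   # amplitude of the fast formation channel
    da2: float  # amplitude of the slow formation channel
    k1: float   # fast formation rate constant, > 0
    k1p: float  # slow formation rate constant, > 0
    k2: float   # decay rate constant, > 0

    def __post_init__(self) -> None:
        for name in ("k1", "k1p", "k2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InputError(f"rate constant {name} must be finite and > 0")


def eval_single_exp(params: SingleExpParams, t) -> np.ndarray:
    """Evaluate ``A0 - A exp(-k t)`` for scalar or array ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be non-negative")
    return params.a0 - params.a * np.exp(-params.k * t)


def _bateman_channel(amp: float, kf: float, k2: float, t: np.ndarray) -> np.ndarray:
    """One rise/decay channel, with the analytic k2 -> kf limit."""
    if abs(k2 - kf) / kf < DEGENERATE_RTOL:
        return amp * kf * t * np.exp(-kf * t)
    return amp * (kf / (k2 - kf)) * (np.exp(-kf * t) - np.exp(-k2 * t))


def eval_rise_decay(params: RiseDecayParams, t) -> np.ndarray:
    """Evaluate the two-channel rise / common-decay model for ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be non-negative")
    return (
        params.a0
        + _bateman_channel(params.da, params.k1, params.k2, t)
        + _bateman_channel(params.da2, params.k1p, params.k2, t)
    )
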