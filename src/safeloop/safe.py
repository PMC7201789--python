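"""SAFE layer: sliding-mode conditioning of the glucose reference.

The safety auxiliary feedback element watches the IOB estimate against a
limit IOB̄.  A sliding function

    sigma = (IOB_hat - IOB_bar) + tau * (dIOB_hat/dt - dIOB_bar/dt)

drives a switching law ``omega = W if sigma > 0 else 0`` whose discontinuous
output is smoothed by a first-order filter acting on the glucose reference:

    dG_rf/dt = -lam * (G_rf - G_r) + omega

While the constraint is violated the filtered reference G_rf rises far above
the setpoint G_r, which makes the PD controller cut insulin; once the IOB
estimate is back below its limit, G_rf relaxes exponentially to G_r at rate
``lam``.  The filter is advanced with the exact zero-order-hold update so the
relaxation is exactly exponential at any step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class SafeParams:
    """tau: sliding-surface time constant (min); W: switching amplitude
    (mg/dl); lam: reference-filter rate (1/min)."""

    tau: float = 10.0
    w: float = 350.0
    lam: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.w <= 0 or self.lam <= 0:
            raise ValueError("tau, W and lam must all be positive")


@dataclass(frozen=True)
class SafeState:
    """g_rf: conditioned reference (mg/dl), initialized at G_r;
    prev_iob_hat / prev_iob_bar: previous-sample values for the backward
    differences in the sliding function."""

    g_rf: float
    prev_iob_hat: float = 0.0
    prev_iob_bar: float = 0.0


def sliding_sigma(
    iob_hat: float,
    iob_bar: float,
    d_iob_hat: float,
    d_iob_bar: float,
    tau: float,
) -> float:
    """Sliding function value (U); positive means the constraint is violated."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return (iob_hat - iob_bar) + tau * (d_iob_hat - d_iob_bar)


def switching(sigma: float, w: float) -> float:
    """Discontinuous action (mg/dl): W for sigma strictly positive, else 0."""
    if w <= 0:
        raise ValueError("W must be positive")
    return w if sigma > 0 else 0.0


def filter_reference(
    state: SafeState, g_r: float, omega: float, lam: float, dt: float
) -> SafeState:
    """Advance the reference filter ``dt`` minutes with ``omega`` held.

    Exact update of the first-order ODE: the filter state moves toward the
    momentary equilibrium ``G_r + omega/lam`` with time constant ``1/lam``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if lam <= 0:
        raise ValueError("lam must be positive")
    target = g_r + omega / lam
    g_rf = target + (state.g_rf - target) * math.exp(-lam * dt)
    return replace(state, g_rf=g_rf)
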