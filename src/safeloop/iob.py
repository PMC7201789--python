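"""Insulin-on-board (IOB) estimation.

Subcutaneously delivered insulin is absorbed through a two-compartment linear
chain with a single elimination rate constant ``K_DIA`` tied to the duration
of insulin action:

    dC1/dt = u_d(t) - K_DIA * C1
    dC2/dt = K_DIA * (C1 - C2)
    IOB(t) = C1 + C2

with ``u_d`` the delivered insulin rate in U/min and both compartments in U.
Boluses enter as impulses on C1.  The same kinetics, applied offline to an
augmented 60-g meal bolus, yield the clinically validated fixed IOB
constraint used by one of the comparison arms.

Two integration backends are provided: a fixed-step explicit Heun update
(default, 1-min internal step matching pump resolution) and the exact
zero-order-hold solution of the linear system, used as the numerical oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .profiles import BasalProfile


@dataclass(frozen=True)
class IOBParams:
    """Kinetic parameters of the IOB estimator.

    k_dia : elimination rate constant, 1/min (default 0.013).
    """

    k_dia: float = 0.013

    def __post_init__(self) -> None:
        if self.k_dia <= 0:
            raise ValueError("k_dia must be positive")


@dataclass(frozen=True)
class IOBState:
    """Insulin masses (U) in the two absorption compartments."""

    c1: float = 0.0
    c2: float = 0.0


def iob_estimate(state: IOBState) -> float:
    """IOB estimate in U: the total insulin mass still in the chain."""
    return state.c1 + state.c2


def add_bolus(state: IOBState, bolus_u: float) -> IOBState:
    """Inject a bolus (U) as an instantaneous increment of compartment 1."""
    if bolus_u < 0:
        raise ValueError("bolus must be non-negative")
    return IOBState(state.c1 + bolus_u, state.c2)


def _step_exact(c1: float, c2: float, u: float, dt: float, k: float) -> tuple[float, float]:
    # zero-order-hold solution: decompose into the constant particular
    # solution (u/k, u/k) plus the defective-eigenvalue homogeneous part
    ss = u / k
    a = c1 - ss
    b = c2 - ss
    e = math.exp(-k * dt)
    return ss + a * e, ss + (b + k * dt * a) * e


def _step_heun(c1: float, c2: float, u: float, dt: float, k: float) -> tuple[float, float]:
    d1a = u - k * c1
    d2a = k * (c1 - c2)
    p1 = c1 + dt * d1a
    p2 = c2 + dt * d2a
    d1b = u - k * p1
    d2b = k * (p1 - p2)
    return c1 + 0.5 * dt * (d1a + d1b), c2 + 0.5 * dt * (d2a + d2b)


def step_iob(
    state: IOBState,
    u_d: float,
    dt: float,
    params: IOBParams,
    method: str = "heun",
    substep: float = 1.0,
) -> IOBState:
    """Advance the estimator ``dt`` minutes under a held delivery rate.

    Parameters
    ----------
    u_d : held insulin delivery rate, U/min (boluses go through
        :func:`add_bolus` before stepping, not through this rate).
    method : "heun" (fixed-step explicit, internal step ``substep``) or
        "exact" (closed-form zero-order-hold update).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if u_d < 0:
        raise ValueError("delivery rate must be non-negative")
    k = params.k_dia
    c1, c2 = state.c1, state.c2
    if method == "exact":
        c1, c2 = _step_exact(c1, c2, u_d, dt, k)
    elif method == "heun":
        n = max(1, int(round(dt / substep)))
        h = dt / n
        for _ in range(n):
            c1, c2 = _step_heun(c1, c2, u_d, h, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    return IOBState(c1, c2)


def steady_state_iob(u_rate_per_min: float, params: IOBParams) -> float:
    """IOB reached under a constant infusion ``u`` U/min: ``2 u / K_DIA``."""
    if u_rate_per_min < 0:
        raise ValueError("infusion rate must be non-negative")
    return 2.0 * u_rate_per_min / params.k_dia


def basal_steady_state(u_rate_per_min: float, params: IOBParams) -> IOBState:
    """Compartment state under a long-held constant infusion (U/min)."""
    ss = u_rate_per_min / params.k_dia
    return IOBState(ss, ss)


def fixed_meal_constraint(
    basal_profile: BasalProfile,
    i2c: float,
    meal_time_min: float,
    params: IOBParams | None = None,
    grams: float = 60.0,
    horizon_min: float = 90.0,
) -> float:
    """Offline fixed IOB constraint from an augmented meal bolus.

    Starting from the basal steady state of the estimator, an augmented bolus
    (standard bolus ``grams/I2C`` plus the basal insulin scheduled over the
    following hour) is injected and the kinetics are run forward with zero
    delivery; the IOB estimate ``horizon_min`` (default 90) minutes later is
    the constraint.  This reproduces, for a 60-g meal, the single fixed limit
    validated clinically, and is the limit used by the "fixed" arm.
    """
    if params is None:
        params = IOBParams()
    if i2c <= 0:
        raise ValueError("I2C must be positive")
    if grams < 0:
        raise ValueError("grams must be non-negative")
    u_b = basal_profile.rate_per_min_at(meal_time_min)
    bolus = grams / i2c + basal_profile.insulin_between(meal_time_min, meal_time_min + 60.0)
    state = add_bolus(basal_steady_state(u_b, params), bolus)
    state = step_iob(state, 0.0, horizon_min, params, method="exact")
    return iob_estimate(state)
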