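"""Inner loop: PD controller with insulin feedback and meal boluses.

The commanded delivery combines a proportional-derivative correction around
the conditioned reference, the feed-forward basal profile, announced-meal
boluses, and an insulin-feedback (IFB) term that mimics beta-cell
self-suppression by subtracting a scaled estimate of the plasma-insulin
deviation from basal:

    u_pd = Kp * [(G - G_rf) + Td * dG/dt]
    u_d  = max(0, u_pd + u_basal - gamma * Ip_hat)

Sign convention: insulin delivery increases when glucose is above the
reference.  This is the convention under which the SAFE layer works — raising
G_rf *reduces* the insulin suggestion — and is used throughout.

The meal bolus is an augmented standard bolus: carbohydrates over the
insulin-to-carb ratio, a correction term toward the reference, plus the basal
insulin scheduled over the next M_CHO minutes (so a 60-g meal borrows the
next hour of basal).
"""

from __future__ import annotations

from dataclasses import dataclass

from .iob import _step_exact, _step_heun
from .profiles import BasalProfile

#: divisor of the TDI-based proportional-gain heuristic, (mg/dl)*min/U
KP_TDI_DIVISOR = 2250.0


@dataclass(frozen=True)
class ControllerParams:
    """Inner-loop tuning.

    kp : proportional gain, U/min per mg/dl (default TDI/2250)
    td : derivative time, min
    g_r : glucose setpoint, mg/dl
    gamma : insulin-feedback gain (dimensionless scaling on the estimated
        plasma-insulin deviation in U)
    i2c : insulin-to-carb ratio, g/U;  cf : correction factor, mg/dl per U
    tdi : total daily insulin, U
    k_ifb : rate constant of the IFB estimator chain, 1/min (defaults to the
        IOB elimination constant — the estimator tracks the same kinetics,
        restricted to deviations from basal)
    """

    tdi: float
    i2c: float
    cf: float
    kp: float | None = None
    td: float = 90.0
    g_r: float = 100.0
    gamma: float = 0.42
    k_ifb: float = 0.013

    def __post_init__(self) -> None:
        if self.tdi <= 0 or self.i2c <= 0 or self.cf <= 0:
            raise ValueError("TDI, I2C and CF must be positive")
        if self.kp is not None and self.kp <= 0:
            raise ValueError("Kp must be positive")
        if self.td < 0 or self.g_r <= 0 or self.gamma < 0 or self.k_ifb <= 0:
            raise ValueError("invalid controller parameter")

    @property
    def kp_effective(self) -> float:
        return self.kp if self.kp is not None else self.tdi / KP_TDI_DIVISOR


@dataclass(frozen=True)
class PlasmaInsulinEstimate:
    """Two-compartment estimate of plasma-insulin deviation from basal.

    Driven by (u_d - u_basal); zero at basal steady state.  ``ip_hat`` is the
    chain total, in U of insulin mass above (or below) the basal load.
    """

    d1: float = 0.0
    d2: float = 0.0

    @property
    def ip_hat(self) -> float:
        return self.d1 + self.d2


def pd_action(g_rf: float, g: float, dgdt: float, params: ControllerParams) -> float:
    """PD control action in U/min (may be negative; clamping happens in
    :func:`final_action`)."""
    return params.kp_effective * ((g - g_rf) + params.td * dgdt)


def meal_bolus(
    m_cho: float,
    g: float,
    params: ControllerParams,
    basal_profile: BasalProfile,
    t_min: float,
) -> float:
    """Augmented meal bolus (U) for an announced meal of ``m_cho`` grams.

    Standard carb coverage + glucose correction + the basal insulin scheduled
    over the next ``m_cho`` minutes; the correction term may be negative but
    the total is clamped at zero.
    """
    if m_cho < 0:
        raise ValueError("announced carbohydrates must be non-negative")
    if m_cho == 0:
        return 0.0
    carb = m_cho / params.i2c
    corr = (g - params.g_r) / params.cf
    basal = basal_profile.insulin_between(t_min, t_min + m_cho)
    return max(0.0, carb + corr + basal)


def ifb_add_bolus(est: PlasmaInsulinEstimate, bolus_u: float) -> PlasmaInsulinEstimate:
    """Boluses are delivery above basal: inject into the first compartment."""
    return PlasmaInsulinEstimate(est.d1 + bolus_u, est.d2)


def ifb_update(
    est: PlasmaInsulinEstimate,
    u_d: float,
    u_basal: float,
    dt: float,
    k: float = 0.013,
    method: str = "heun",
) -> PlasmaInsulinEstimate:
    """Advance the IFB estimator ``dt`` minutes under held rates.

    The deviation input (u_d - u_basal) may be negative (delivery suspended
    below basal), so the compartments are signed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = u_d - u_basal
    if method == "exact":
        d1, d2 = _step_exact(est.d1, est.d2, u, dt, k)
    else:
        n = max(1, int(round(dt)))
        h = dt / n
        d1, d2 = est.d1, est.d2
        for _ in range(n):
            d1, d2 = _step_heun(d1, d2, u, h, k)
    return PlasmaInsulinEstimate(d1, d2)


def final_action(u_pd: float, u_basal: float, gamma: float, ip_hat: float) -> float:
    """Commanded delivery rate, U/min: PD + basal - insulin feedback, clamped
    at zero (a pump cannot remove insulin)."""
    return max(0.0, u_pd + u_basal - gamma * ip_hat)
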