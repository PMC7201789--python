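"""Surrogate virtual patient: a minimal glucoregulatory model.

A Bergman-type minimal model with single-compartment gut absorption and
two-compartment subcutaneous insulin kinetics.  States:

    Isc1, Isc2 : subcutaneous insulin depots (U);  dIsc1 = u_d - k_sc*Isc1,
                 dIsc2 = k_sc*(Isc1 - Isc2)
    Ip         : plasma insulin load (U);          dIp   = -k_e*Ip + k_sc*Isc2
    X          : remote insulin action (U);        dX    = -p2*(X - Ip)
    Q          : gut glucose mass (mg);            dQ    = -k_abs*Q  (+ meals)
    G          : plasma glucose (mg/dl);
        dG = -p1*(G - G_end) - S_I(t)*X*G + f*k_abs*Q/V_g

``G_end`` is the insulin-free glucose equilibrium (glucose effectiveness
pulls toward it at rate ``p1``); insulin lowers glucose multiplicatively
through the remote action X with sensitivity ``S_I``.  Insulin sensitivity
carries a 24-h sinusoidal variation of +/-30% with a per-patient random
phase, which shifts the true basal insulin requirement over the day; meal
absorption parameters are re-drawn within +/-30% of nominal at every meal.

This plant is deliberately simple and public: it reproduces the qualitative
behaviours a hybrid closed-loop controller must cope with (meal rise,
insulin-driven fall, circadian requirement drift, absorption variability)
and is not claimed to match any licensed simulator's numerics.

The cohort generator samples physiology, then derives an internally
consistent open-loop therapy: CF by the 1700 rule, I2C by the 450 rule, and
a basal rate placing the fasting steady state at the sampled basal glucose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .profiles import BasalProfile

MIN_PER_DAY = 1440.0

#: relative amplitude of the circadian insulin-sensitivity oscillation
CIRCADIAN_AMPLITUDE = 0.3
#: half-width of the per-meal absorption-parameter perturbation
MEAL_PERTURBATION = 0.3


@dataclass(frozen=True)
class PatientParams:
    """Physiology plus the open-loop therapy block.

    Rates are 1/min; volumes dl; insulin masses U; glucose mg/dl.
    """

    patient_id: int
    g_b: float            # fasting glucose at the programmed basal rate
    g_end: float          # insulin-free glucose equilibrium
    p1: float             # glucose effectiveness
    p2: float             # remote-insulin equilibration rate
    k_e: float            # plasma insulin elimination
    k_sc: float           # subcutaneous absorption
    k_abs: float          # meal (gut) absorption
    v_g: float            # glucose distribution volume, dl
    f_bio: float          # carbohydrate bioavailability, fraction
    s_i: float            # insulin sensitivity, 1/(U*min)
    # therapy block
    tdi: float            # total daily insulin, U
    i2c: float            # insulin-to-carb ratio, g/U
    cf: float             # correction factor, mg/dl per U
    basal_profile: BasalProfile

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "k_e", "k_sc", "k_abs", "v_g", "s_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f_bio <= 1:
            raise ValueError("bioavailability must be in (0, 1]")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "patient_id", "g_b", "g_end", "p1", "p2", "k_e", "k_sc", "k_abs",
            "v_g", "f_bio", "s_i", "tdi", "i2c", "cf",
        )}
        d["basal_profile"] = self.basal_profile.to_segments()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientParams":
        d = dict(d)
        d["basal_profile"] = BasalProfile.from_segments(d["basal_profile"])
        return cls(**d)


@dataclass(frozen=True)
class PatientState:
    g: float
    x: float
    ip: float
    isc1: float
    isc2: float
    q_gut: float


def circadian_param(t_min: float, q0: float, phase: float) -> float:
    """24-h sinusoidal parameter variation with a uniform random phase.

    q(t) = q0 * (1 + 0.3 * sin(2*pi*t/1440 + 2*pi*phase)); bounded in
    [0.7*q0, 1.3*q0].
    """
    if q0 <= 0:
        raise ValueError("nominal parameter value must be positive")
    return q0 + CIRCADIAN_AMPLITUDE * q0 * math.sin(
        2.0 * math.pi * t_min / MIN_PER_DAY + 2.0 * math.pi * phase
    )


def perturb_meal_params(params: PatientParams, rng: np.random.Generator) -> PatientParams:
    """Re-draw absorption-class parameters uniformly within +/-30% of nominal.

    Applied at each meal ingestion and held until the next meal; draws are
    around the *nominal* values so perturbations do not compound.
    """
    lo, hi = 1.0 - MEAL_PERTURBATION, 1.0 + MEAL_PERTURBATION
    return replace(
        params,
        k_abs=params.k_abs * rng.uniform(lo, hi),
        k_sc=params.k_sc * rng.uniform(lo, hi),
    )


def basal_steady_state(params: PatientParams, u_basal_per_min: float) -> PatientState:
    """Closed-form steady state of the plant under a constant delivery rate."""
    isc = u_basal_per_min / params.k_sc
    ip = u_basal_per_min / params.k_e
    x = ip
    g = params.p1 * params.g_end / (params.p1 + params.s_i * x)
    return PatientState(g=g, x=x, ip=ip, isc1=isc, isc2=isc, q_gut=0.0)


def ingest_meal(state: PatientState, grams: float) -> PatientState:
    """Add a meal's carbohydrates (g) to the gut compartment."""
    if grams < 0:
        raise ValueError("meal grams must be non-negative")
    return replace(state, q_gut=state.q_gut + grams * 1000.0)


def inject_bolus(state: PatientState, bolus_u: float) -> PatientState:
    """Deposit a bolus (U) into the first subcutaneous compartment."""
    if bolus_u < 0:
        raise ValueError("bolus must be non-negative")
    return replace(state, isc1=state.isc1 + bolus_u)


def _deriv(
    s: tuple[float, float, float, float, float, float],
    p: PatientParams,
    u_d: float,
    s_i_t: float,
) -> tuple[float, float, float, float, float, float]:
    g, x, ip, isc1, isc2, q = s
    d_isc1 = u_d - p.k_sc * isc1
    d_isc2 = p.k_sc * (isc1 - isc2)
    d_ip = -p.k_e * ip + p.k_sc * isc2
    d_x = -p.p2 * (x - ip)
    d_q = -p.k_abs * q
    d_g = -p.p1 * (g - p.g_end) - s_i_t * x * g + p.f_bio * p.k_abs * q / p.v_g
    return d_g, d_x, d_ip, d_isc1, d_isc2, d_q


def patient_step(
    state: PatientState,
    params: PatientParams,
    u_d: float,
    dt: float,
    t_min: float = 0.0,
    s_i_phase: float | None = None,
) -> PatientState:
    """Advance the plant one Heun step of ``dt`` minutes under held delivery.

    ``s_i_phase`` enables the circadian sensitivity oscillation (None = off).
    Meals and boluses are injected beforehand via :func:`ingest_meal` /
    :func:`inject_bolus`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if u_d < 0:
        raise ValueError("delivery rate must be non-negative")
    if s_i_phase is None:
        si0 = si1 = params.s_i
    else:
        si0 = circadian_param(t_min, params.s_i, s_i_phase)
        si1 = circadian_param(t_min + dt, params.s_i, s_i_phase)
    s = (state.g, state.x, state.ip, state.isc1, state.isc2, state.q_gut)
    k1 = _deriv(s, params, u_d, si0)
    pred = tuple(v + dt * d for v, d in zip(s, k1))
    k2 = _deriv(pred, params, u_d, si1)
    new = tuple(v + 0.5 * dt * (a + b) for v, a, b in zip(s, k1, k2))
    if not all(math.isfinite(v) for v in new):
        raise FloatingPointError(
            f"patient {params.patient_id}: non-finite state at t={t_min} min "
            f"(u_d={u_d}, state={new})"
        )
    return PatientState(*new)


def cgm_read(state: PatientState, noise_sd: float = 0.0, rng: np.random.Generator | None = None) -> float:
    """CGM glucose reading: plasma glucose plus optional Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if noise_sd == 0.0 or rng is None:
        return state.g
    return state.g + noise_sd * rng.standard_normal()


# ---------------------------------------------------------------------------
# cohort generation

_RANGES = {
    "tdi": (30.0, 60.0),
    "g_b": (110.0, 130.0),
    "g_end": (280.0, 340.0),
    "p1": (0.0035, 0.005),
    "p2": (0.015, 0.03),
    "k_e": (0.10, 0.16),
    "k_sc": (0.020, 0.033),
    "k_abs": (0.010, 0.020),
    "v_g": (115.0, 155.0),
}

CF_RULE = 1700.0
I2C_RULE = 450.0


def _sample_patient(pid: int, rng: np.random.Generator) -> PatientParams:
    draw = {k: rng.uniform(*v) for k, v in _RANGES.items()}
    cf = CF_RULE / draw["tdi"]
    i2c = I2C_RULE / draw["tdi"]
    # sensitivity consistent with the correction factor: a 1-U bolus produces
    # ~CF mg/dl of glucose-lowering exposure (linearized at g_b)
    s_i = cf * draw["k_e"] / draw["g_b"]
    # basal rate placing the fasting equilibrium at g_b
    u_b = draw["p1"] * (draw["g_end"] - draw["g_b"]) / cf  # U/min
    return PatientParams(
        patient_id=pid,
        g_b=draw["g_b"],
        g_end=draw["g_end"],
        p1=draw["p1"],
        p2=draw["p2"],
        k_e=draw["k_e"],
        k_sc=draw["k_sc"],
        k_abs=draw["k_abs"],
        v_g=draw["v_g"],
        f_bio=1.0,
        s_i=s_i,
        tdi=draw["tdi"],
        i2c=i2c,
        cf=cf,
        basal_profile=BasalProfile.flat(60.0 * u_b),
    )


def _passes_checks(p: PatientParams) -> bool:
    u_b = p.basal_profile.rate_per_min_at(0.0)
    basal_total = u_b * MIN_PER_DAY
    if not 0.2 <= basal_total / p.tdi <= 0.7:
        return False
    if not 0.2 <= p.basal_profile.rate_at(0.0) <= 2.5:
        return False
    # basal steady state must hold: 24 h at basal delivery, variability off
    st = basal_steady_state(p, u_b)
    for i in range(288):
        st = patient_step(st, p, u_b, 5.0, t_min=5.0 * i)
    return abs(st.g - p.g_b) <= 10.0


def generate_cohort(n: int, seed: int) -> list[PatientParams]:
    """Deterministically sample ``n`` virtual patients.

    Rejects and resamples any draw whose therapy is internally inconsistent
    (basal fraction of TDI outside [0.2, 0.7] or basal rate implausible) or
    that fails the basal steady-state check (fasting glucose within
    +/-10 mg/dl of its target over 24 h at basal delivery).
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    cohort: list[PatientParams] = []
    attempts = 0
    while len(cohort) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cohort sampling failed: ranges appear infeasible")
        cand = _sample_patient(len(cohort), rng)
        if _passes_checks(cand):
            cohort.append(cand)
    return cohort


def save_cohort(cohort: list[PatientParams], path: str) -> None:
    import json

    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in cohort], fh, indent=1)


def load_cohort(path: str) -> list[PatientParams]:
    import json

    with open(path) as fh:
        return [PatientParams.from_dict(d) for d in json.load(fh)]
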