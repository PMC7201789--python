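"""Closed-loop simulation engine.

Wires one virtual patient to the PD+IFB controller, the SAFE layer and one
of four IOB-limit strategies ("arms"):

* ``drb`` — dynamic rule-based limit (fasting baseline + postprandial rules)
* ``baseline_only`` — the fasting baseline with no postprandial raise
* ``fixed`` — the single offline 60-g constraint, held for the whole run
* ``unconstrained`` — no IOB limit (the SAFE layer never engages)

The plant advances at a 1-min internal step; CGM sampling, the controller,
the switching law and the DRB rules run every 5 min (configurable).  Meal
boluses are impulses routed simultaneously to the plant's subcutaneous
depot, the IOB estimator and the insulin-feedback estimator.

The per-sample trace is returned as a DataFrame with the fixed schema
``time_min, G, G_rf, u_d, bolus, IOB_hat, IOB_bar, sigma, omega, arm,
patient_id``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import iob as iob_mod
from . import patient as pat_mod
from .config import LoopConfig
from .controller import (
    ControllerParams,
    PlasmaInsulinEstimate,
    final_action,
    ifb_add_bolus,
    ifb_update,
    meal_bolus,
    pd_action,
)
from .drb import (
    ConstraintState,
    DRBParams,
    KIOBSchedule,
    baseline_limit,
    current_limit,
    on_meal_announced,
)
from .iob import IOBParams, add_bolus, iob_estimate, step_iob
from .patient import PatientParams
from .profiles import parse_clock
from .safe import sliding_sigma, switching

ARMS = ("drb", "fixed", "baseline_only", "unconstrained")

TRACE_COLUMNS = [
    "time_min", "G", "G_rf", "u_d", "bolus",
    "IOB_hat", "IOB_bar", "sigma", "omega", "arm", "patient_id",
]


def run_closed_loop(
    patient: PatientParams,
    meals: list[tuple[float, float, float]],
    duration_min: float,
    arm: str,
    cfg: LoopConfig | None = None,
    s_i_phase: float | None = 0.0,
    perturb_rng: np.random.Generator | None = None,
    cgm_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one (patient, arm) pair over a meal schedule.

    Parameters
    ----------
    meals : list of (time_min, true_grams, announced_grams), sorted by time;
        times are snapped to the controller sampling grid.
    s_i_phase : circadian phase of the insulin-sensitivity oscillation in
        [0, 1); None disables the oscillation.
    perturb_rng : stream for the per-meal +/-30% absorption perturbation
        (None disables it).
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    if cfg is None:
        cfg = LoopConfig()
    prof = patient.basal_profile
    ts = cfg.sample_period
    iobp = IOBParams(cfg.k_dia)
    ctl = ControllerParams(
        tdi=patient.tdi, i2c=patient.i2c, cf=patient.cf, kp=cfg.kp,
        td=cfg.td, g_r=cfg.g_r, gamma=cfg.gamma, k_ifb=cfg.k_dia,
    )
    sched = KIOBSchedule(
        day_gain=cfg.k_iob_day, night_gain=cfg.k_iob_night,
        day_start=parse_clock(cfg.day_start), night_start=parse_clock(cfg.night_start),
    )
    drbp = DRBParams(cfg.g_trigger, cfg.g_release, cfg.t_iob_slope)

    iob_bar_fixed = math.nan
    if arm == "fixed":
        iob_bar_fixed = iob_mod.fixed_meal_constraint(prof, patient.i2c, 720.0, iobp)

    meals = sorted(
        (round(t / ts) * ts, tg, ag) for t, tg, ag in meals
    )

    u_b0 = prof.rate_per_min_at(0.0)
    pstate = pat_mod.basal_steady_state(patient, u_b0)
    iob_state = iob_mod.basal_steady_state(u_b0, iobp)
    ifb_est = PlasmaInsulinEstimate()
    drb_state = ConstraintState()
    g_rf = cfg.g_r
    prev_iob_hat = iob_estimate(iob_state)
    prev_limit = math.inf
    g_hist: list[float] = []
    meal_idx = 0
    nsub = max(1, int(round(ts / cfg.plant_dt)))
    h = ts / nsub
    eff = patient
    exp_lam = math.exp(-cfg.lam * ts)

    n_samples = int(round(duration_min / ts))
    rows = []
    for k in range(n_samples):
        t = k * ts
        g_cgm = pat_mod.cgm_read(pstate, cfg.cgm_noise_sd, cgm_rng)
        g_hist.append(g_cgm)
        if k == 0:
            dgdt = 0.0
        elif cfg.smooth_derivative and k >= 3:
            sm_now = (g_hist[-1] + g_hist[-2] + g_hist[-3]) / 3.0
            sm_prev = (g_hist[-2] + g_hist[-3] + g_hist[-4]) / 3.0
            dgdt = (sm_now - sm_prev) / ts
        else:
            dgdt = (g_hist[-1] - g_hist[-2]) / ts

        bolus = 0.0
        while meal_idx < len(meals) and meals[meal_idx][0] <= t:
            _, true_g, ann_g = meals[meal_idx]
            meal_idx += 1
            bolus += meal_bolus(ann_g, g_cgm, ctl, prof, t)
            pstate = pat_mod.ingest_meal(pstate, true_g)
            if perturb_rng is not None:
                eff = pat_mod.perturb_meal_params(patient, perturb_rng)
            if ann_g > 0:
                drb_state = on_meal_announced(drb_state, t, ann_g, drbp)
        if bolus > 0.0:
            pstate = pat_mod.inject_bolus(pstate, bolus)
            iob_state = add_bolus(iob_state, bolus)
            ifb_est = ifb_add_bolus(ifb_est, bolus)

        iob_hat = iob_estimate(iob_state)
        base = baseline_limit(t, prof, sched, cfg.k_dia)
        if arm == "drb":
            limit, drb_state = current_limit(
                drb_state, t, g_cgm, prev_iob_hat, base, drbp
            )
        elif arm == "baseline_only":
            limit = base
        elif arm == "fixed":
            limit = iob_bar_fixed
        else:
            limit = math.inf

        if math.isinf(limit):
            sigma = -math.inf
            omega = 0.0
        else:
            d_hat = (iob_hat - prev_iob_hat) / ts if k > 0 else 0.0
            # the limit is piecewise constant; its backward difference is
            # zeroed on jumps (DRB raise/release, profile or day/night steps)
            d_bar = 0.0
            sigma = sliding_sigma(iob_hat, limit, d_hat, d_bar, cfg.tau)
            omega = switching(sigma, cfg.w)

        # exact first-order update of the conditioned reference, omega held
        target = cfg.g_r + omega / cfg.lam
        g_rf = target + (g_rf - target) * exp_lam

        u_basal = prof.rate_per_min_at(t)
        u_pd = pd_action(g_rf, g_cgm, dgdt, ctl)
        u_d = final_action(u_pd, u_basal, ctl.gamma, ifb_est.ip_hat)

        rows.append((t, g_cgm, g_rf, u_d, bolus, iob_hat, limit, sigma, omega))

        for j in range(nsub):
            pstate = pat_mod.patient_step(
                pstate, eff, u_d, h, t_min=t + j * h, s_i_phase=s_i_phase
            )
        iob_state = step_iob(iob_state, u_d, ts, iobp, method=cfg.iob_method)
        ifb_est = ifb_update(ifb_est, u_d, u_basal, ts, ctl.k_ifb)
        prev_iob_hat = iob_hat
        prev_limit = limit

    df = pd.DataFrame(rows, columns=TRACE_COLUMNS[:9])
    df["arm"] = arm
    df["patient_id"] = patient.patient_id
    return df
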