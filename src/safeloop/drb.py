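"""Dynamic rule-based (DRB) tuning of the IOB limit.

The IOB limit fed to the SAFE layer is made time-varying by combining two
strategies:

* **Fasting baseline** — the limit tracks a gain times the steady-state IOB
  that the patient's programmed basal rate would produce:

      IOB_bl(t) = K_IOB(t) * 2 * u_basal(t) / (60 * K_DIA)

  with ``u_basal`` in U/h.  ``K_IOB = 1`` means the closed loop may hold at
  most the open-loop therapy's IOB; the defaults allow 30% more by day
  (06:00-23:00) and 10% more by night (23:00-06:00).

* **Postprandial raise** — after an announced meal the bolus itself violates
  the baseline limit and the SAFE layer suspends delivery.  From
  ``T_IOB = 1.5 * M_CHO`` minutes after the meal, glucose readings are
  evaluated: the first time BG exceeds the trigger threshold, the limit is
  raised once per meal to ``max(previous-sample IOB estimate, baseline)`` and
  held there until BG falls below the release threshold, when the limit
  returns to the baseline and the meal window closes.

The state machine is driven once per controller sample through
:func:`current_limit`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .profiles import MIN_PER_DAY, BasalProfile, parse_clock


@dataclass(frozen=True)
class KIOBSchedule:
    """Day/night gains on the fasting IOB baseline, switched by local clock."""

    day_gain: float = 1.3
    night_gain: float = 1.1
    day_start: float = parse_clock("06:00")
    night_start: float = parse_clock("23:00")

    def __post_init__(self) -> None:
        if self.day_gain <= 0 or self.night_gain <= 0:
            raise ValueError("K_IOB gains must be positive")

    def gain_at(self, t_min: float) -> float:
        tod = t_min % MIN_PER_DAY
        if self.day_start <= tod < self.night_start:
            return self.day_gain
        return self.night_gain


@dataclass(frozen=True)
class DRBParams:
    """g_trigger: BG above which the postprandial limit is raised (mg/dl);
    g_release: BG below which it is released (mg/dl);
    t_iob_slope: evaluation delay per announced gram (min/g)."""

    g_trigger: float = 150.0
    g_release: float = 140.0
    t_iob_slope: float = 1.5

    def __post_init__(self) -> None:
        if not (self.g_trigger >= self.g_release > 0):
            raise ValueError("need G_trigger >= G_release > 0")
        if self.t_iob_slope <= 0:
            raise ValueError("t_iob_slope must be positive")


@dataclass(frozen=True)
class ConstraintState:
    """Postprandial state machine.

    pp_state : a meal's postprandial window is active.
    flag_pp : the raised limit has been computed for this meal (at most once).
    meal_time : absolute time (min) of the last announced meal.
    t_iob : evaluation delay for that meal (min).
    iob_bar_pp : stored postprandial limit (U).
    """

    pp_state: bool = False
    flag_pp: bool = False
    meal_time: float = 0.0
    t_iob: float = 0.0
    iob_bar_pp: float = 0.0


def baseline_limit(
    t_min: float,
    basal_profile: BasalProfile,
    schedule: KIOBSchedule,
    k_dia: float,
) -> float:
    """Fasting IOB-limit baseline (U) at absolute time ``t_min``."""
    if k_dia <= 0:
        raise ValueError("k_dia must be positive")
    u_basal_u_per_h = basal_profile.rate_at(t_min)
    return schedule.gain_at(t_min) * 2.0 * u_basal_u_per_h / (60.0 * k_dia)


def t_iob(m_cho: float, slope: float = 1.5) -> float:
    """Minutes after the meal before the raise rule starts evaluating BG."""
    if m_cho < 0:
        raise ValueError("meal size must be non-negative")
    return slope * m_cho


def on_meal_announced(
    state: ConstraintState, t_min: float, m_cho_announced: float, params: DRBParams
) -> ConstraintState:
    """Open (or reset to) a postprandial window for an announced meal.

    A meal announced during an active window replaces it: the evaluation
    clock restarts from the new meal.
    """
    if m_cho_announced <= 0:
        raise ValueError("announced meal must have positive grams")
    return ConstraintState(
        pp_state=True,
        flag_pp=False,
        meal_time=t_min,
        t_iob=t_iob(m_cho_announced, params.t_iob_slope),
        iob_bar_pp=0.0,
    )


def current_limit(
    state: ConstraintState,
    t_min: float,
    g: float,
    iob_hat_prev: float,
    baseline: float,
    params: DRBParams,
) -> tuple[float, ConstraintState]:
    """One per-sample evaluation of the rule set.

    Returns the IOB limit to apply this sample and the advanced state.
    ``iob_hat_prev`` is the IOB estimate at the previous controller sample,
    which the raise rule captures (the estimate has typically peaked and is
    decaying by the time the rule fires, so the previous sample is the
    conservative choice).
    """
    if not state.pp_state:
        return baseline, state
    if t_min < state.meal_time + state.t_iob:
        # bolus-decay phase: the baseline stays in force and the bolus itself
        # violates it, engaging the SAFE layer
        return baseline, state
    if state.flag_pp:
        if g > params.g_release:
            return state.iob_bar_pp, state
        return baseline, ConstraintState()  # release: window closed
    if g > params.g_trigger:
        raised = max(iob_hat_prev, baseline)
        return raised, replace(state, flag_pp=True, iob_bar_pp=raised)
    if g <= params.g_release:
        return baseline, ConstraintState()  # never exceeded trigger; close
    return baseline, state  # BG between release and trigger: keep waiting
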