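"""Dynamic rule-based IOB-limit tuner: baseline, delay rule and state machine."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from safeloop.drb import (
    ConstraintState,
    DRBParams,
    KIOBSchedule,
    baseline_limit,
    current_limit,
    on_meal_announced,
    t_iob,
)
from safeloop.iob import IOBParams, basal_steady_state, iob_estimate, step_iob
from safeloop.profiles import BasalProfile

SCHED = KIOBSchedule()
DRBP = DRBParams()
K_DIA = 0.013
FLAT1 = BasalProfile.flat(1.0)


class TestBaseline:
    def test_zero_basal_gives_zero_limit(self):
        assert baseline_limit(720.0, BasalProfile.flat(0.0), SCHED, K_DIA) == 0.0

    def test_day_value(self):
        # 1.3 x steady-state IOB of 1 U/h = 1.3 x 2.5641
        got = baseline_limit(720.0, FLAT1, SCHED, K_DIA)
        assert got == pytest.approx(1.3 * 2.5641, abs=2e-4)
        assert got == pytest.approx(3.333, abs=1e-3)

    def test_night_value_below_day(self):
        night = baseline_limit(23.5 * 60.0, FLAT1, SCHED, K_DIA)
        day = baseline_limit(720.0, FLAT1, SCHED, K_DIA)
        assert night == pytest.approx(1.1 * 2.5641, abs=2e-4)
        assert night < day

    def test_day_night_switch_by_clock(self):
        assert baseline_limit(359.0, FLAT1, SCHED, K_DIA) == pytest.approx(1.1 * 2.5641, abs=2e-4)
        assert baseline_limit(360.0, FLAT1, SCHED, K_DIA) == pytest.approx(1.3 * 2.5641, abs=2e-4)
        assert baseline_limit(1380.0, FLAT1, SCHED, K_DIA) == pytest.approx(1.1 * 2.5641, abs=2e-4)

    def test_unity_gain_matches_open_loop_steady_state(self):
        """K_IOB = 1: running the estimator at exactly basal delivery converges
        to the limit, tying the fasting baseline to open-loop therapy IOB."""
        sched1 = KIOBSchedule(day_gain=1.0, night_gain=1.0)
        limit = baseline_limit(720.0, FLAT1, sched1, K_DIA)
        p = IOBParams(K_DIA)
        s = step_iob(basal_steady_state(0.0, p), 1.0 / 60.0, 3000.0, p, method="exact")
        assert iob_estimate(s) == pytest.approx(limit, rel=1e-6)


def test_t_iob_values():
    assert t_iob(45.0) == pytest.approx(67.5)
    assert t_iob(60.0) == pytest.approx(90.0)
    assert t_iob(0.0) == 0.0
    with pytest.raises(ValueError):
        t_iob(-1.0)


class TestStateMachine:
    BASE = 3.333

    def test_fasting_passes_baseline_through(self):
        limit, state = current_limit(ConstraintState(), 100.0, 120.0, 5.0, self.BASE, DRBP)
        assert limit == self.BASE
        assert not state.pp_state

    def test_meal_announcement_opens_window(self):
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        assert st_.pp_state and not st_.flag_pp
        assert st_.meal_time == 450.0
        assert st_.t_iob == pytest.approx(67.5)

    def test_zero_gram_announcement_rejected(self):
        with pytest.raises(ValueError):
            on_meal_announced(ConstraintState(), 450.0, 0.0, DRBP)

    def test_limit_stays_baseline_before_t_iob(self):
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        limit, st_ = current_limit(st_, 500.0, 220.0, 9.0, self.BASE, DRBP)
        assert limit == self.BASE  # bolus violates it; SAFE engages

    def test_raise_fires_once_with_max_rule(self):
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        # at meal + T_IOB with G > 150: limit = max(prev IOB, baseline)
        limit, st_ = current_limit(st_, 520.0, 160.0, 6.0, self.BASE, DRBP)
        assert limit == 6.0 and st_.flag_pp
        # held while G > 140, no recomputation even if IOB grew
        limit, st_ = current_limit(st_, 525.0, 155.0, 8.0, self.BASE, DRBP)
        assert limit == 6.0

    def test_raise_never_below_baseline(self):
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        limit, st_ = current_limit(st_, 520.0, 160.0, 2.0, self.BASE, DRBP)
        assert limit == self.BASE and st_.iob_bar_pp == self.BASE

    def test_release_below_threshold_closes_window(self):
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        _, st_ = current_limit(st_, 520.0, 160.0, 6.0, self.BASE, DRBP)
        limit, st_ = current_limit(st_, 560.0, 139.0, 5.0, self.BASE, DRBP)
        assert limit == self.BASE
        assert not st_.pp_state and not st_.flag_pp

    def test_no_raise_when_glucose_already_low(self):
        """G <= release at first evaluation: window closes, limit never raised."""
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        limit, st_ = current_limit(st_, 520.0, 120.0, 6.0, self.BASE, DRBP)
        assert limit == self.BASE and not st_.pp_state

    def test_intermediate_band_keeps_waiting(self):
        """G in (release, trigger]: window stays open at baseline limit."""
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        limit, st_ = current_limit(st_, 520.0, 145.0, 6.0, self.BASE, DRBP)
        assert limit == self.BASE and st_.pp_state and not st_.flag_pp
        # later surge above the trigger still raises
        limit, st_ = current_limit(st_, 525.0, 151.0, 6.0, self.BASE, DRBP)
        assert limit == 6.0 and st_.flag_pp

    def test_new_meal_resets_window(self):
        st_ = on_meal_announced(ConstraintState(), 450.0, 45.0, DRBP)
        _, st_ = current_limit(st_, 520.0, 160.0, 6.0, self.BASE, DRBP)
        st_ = on_meal_announced(st_, 530.0, 90.0, DRBP)
        assert st_.meal_time == 530.0 and st_.t_iob == pytest.approx(135.0)
        assert not st_.flag_pp


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    gs=st.lists(st.floats(60.0, 300.0), min_size=5, max_size=80),
    iobs=st.lists(st.floats(0.0, 12.0), min_size=5, max_size=80),
)
def test_single_raise_per_meal_and_piecewise_limit(gs, iobs):
    """Per announced meal: at most one raised value, forming one contiguous
    raised interval, never below the baseline."""
    base = 3.0
    st_ = on_meal_announced(ConstraintState(), 0.0, 60.0, DRBP)
    limits = []
    raised_values = set()
    t = 0.0
    for g, iob_prev in zip(gs, iobs):
        t += 5.0
        limit, st_ = current_limit(st_, 90.0 + t, g, iob_prev, base, DRBP)
        limits.append(limit)
        if limit != base:
            raised_values.add(limit)
            assert limit >= base
    assert len(raised_values) <= 1
    # raised samples are contiguous
    flags = [lim != base for lim in limits]
    if any(flags):
        first, last = flags.index(True), len(flags) - 1 - flags[::-1].index(True)
        assert all(flags[first : last + 1])


def test_param_validation():
    with pytest.raises(ValueError):
        DRBParams(g_trigger=130.0, g_release=140.0)
    with pytest.raises(ValueError):
        KIOBSchedule(day_gain=0.0)
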