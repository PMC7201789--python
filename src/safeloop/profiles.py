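"""Piecewise-constant basal insulin profiles.

An insulin pump delivers a background ("basal") flow of rapid-acting insulin
whose rate is programmed per time-of-day segment, in U/h.  The profile is the
patient's open-loop therapy and is the anchor for both the feed-forward basal
term of the controller and the fasting IOB-limit baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

MIN_PER_DAY = 1440


def parse_clock(hhmm: str) -> float:
    """Convert "HH:MM" to minutes from midnight."""
    parts = hhmm.split(":")
    if len(parts) != 2:
        raise ValueError(f"clock time must be 'HH:MM', got {hhmm!r}")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"clock time out of range: {hhmm!r}")
    return float(h * 60 + m)


def format_clock(minute_of_day: float) -> str:
    m = int(round(minute_of_day)) % MIN_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


@dataclass(frozen=True)
class BasalProfile:
    """24-h piecewise-constant basal rate schedule.

    Parameters
    ----------
    starts : tuple of float
        Segment start times, minutes from midnight, strictly increasing,
        first segment starting at 0 so the whole day is covered.
    rates : tuple of float
        Basal rate of each segment in U/h; non-negative.
    """

    starts: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.rates) or not self.starts:
            raise ValueError("profile needs matching, non-empty starts and rates")
        if self.starts[0] != 0.0:
            raise ValueError("first segment must start at 00:00 to cover the day")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("segment starts must be strictly increasing")
        if any(s >= MIN_PER_DAY for s in self.starts):
            raise ValueError("segment starts must lie within one day")
        if any(r < 0 for r in self.rates):
            raise ValueError("basal rates must be non-negative")

    @classmethod
    def flat(cls, rate_u_per_h: float) -> "BasalProfile":
        return cls((0.0,), (float(rate_u_per_h),))

    @classmethod
    def from_segments(cls, segments: list[dict]) -> "BasalProfile":
        """Build from JSON-style ``[{"start_time": "HH:MM", "rate_U_per_h": x}, ...]``."""
        pairs = sorted((parse_clock(s["start_time"]), float(s["rate_U_per_h"])) for s in segments)
        return cls(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))

    def to_segments(self) -> list[dict]:
        return [
            {"start_time": format_clock(t), "rate_U_per_h": r}
            for t, r in zip(self.starts, self.rates)
        ]

    @classmethod
    def from_json(cls, path: str) -> "BasalProfile":
        with open(path) as fh:
            return cls.from_segments(json.load(fh))

    def rate_at(self, t_min: float) -> float:
        """Basal rate (U/h) at absolute simulation time ``t_min`` (wraps daily)."""
        tod = t_min % MIN_PER_DAY
        rate = self.rates[0]
        for start, r in zip(self.starts, self.rates):
            if tod >= start:
                rate = r
            else:
                break
        return rate

    def rate_per_min_at(self, t_min: float) -> float:
        return self.rate_at(t_min) / 60.0

    def insulin_between(self, t0_min: float, t1_min: float) -> float:
        """Basal insulin (U) scheduled over [t0, t1] minutes, wrapping across days."""
        if t1_min < t0_min:
            raise ValueError("t1 must not precede t0")
        total = 0.0
        t = t0_min
        while t < t1_min - 1e-12:
            tod = t % MIN_PER_DAY
            # end of the current segment
            nxt = MIN_PER_DAY
            for start in self.starts:
                if start > tod + 1e-12:
                    nxt = start
                    break
            seg_end = t + (nxt - tod)
            upto = min(seg_end, t1_min)
            total += self.rate_at(t) / 60.0 * (upto - t)
            t = upto
        return total
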