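"""Glycemic outcome metrics from CGM traces.

Consensus CGM metrics: percent time in ranges (70-140 and 70-180 closed
intervals; <70, <54 and >180 strict), hypoglycemic events (at least 15
consecutive minutes below 70 mg/dl), per-meal glycemic excursion over a 4-h
postprandial window, controller-delivered insulin after the bolus over the
same window, the glucose management indicator

    GMI(%) = 3.31 + 0.02392 * mean glucose [mg/dl]

and control-variability grid analysis (CVGA), which classifies each
patient-day's (minimum BG, maximum BG) pair into zones A (best) through E.

Cohort summaries follow the reporting convention median (25th-75th
percentile), split into daytime (06:00-23:00) and night-time (23:00-06:00)
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HYPO_THRESHOLD = 70.0
HYPO_MIN_DURATION = 15.0
POSTPRANDIAL_HORIZON = 240.0
DAY_START_MIN = 6 * 60
NIGHT_START_MIN = 23 * 60
MIN_PER_DAY = 1440

GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392

CVGA_ZONES = ("A", "B", "C", "D", "E")


def time_in_range(glucose, lo: float, hi: float) -> float:
    """Percent of samples with lo <= G <= hi (closed interval)."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("empty trace")
    if lo >= hi:
        raise ValueError("need lo < hi")
    return 100.0 * np.mean((g >= lo) & (g <= hi))


def time_below(glucose, thresh: float) -> float:
    """Percent of samples strictly below ``thresh``."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("empty trace")
    return 100.0 * np.mean(g < thresh)


def time_above(glucose, thresh: float) -> float:
    """Percent of samples strictly above ``thresh``."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("empty trace")
    return 100.0 * np.mean(g > thresh)


def hypo_events(
    glucose,
    sample_period: float,
    threshold: float = HYPO_THRESHOLD,
    min_duration: float = HYPO_MIN_DURATION,
) -> int:
    """Count hypoglycemic events: maximal runs of consecutive samples
    strictly below ``threshold`` lasting at least ``min_duration`` minutes.

    A run of k consecutive sub-threshold samples spans k*sample_period
    minutes; the run ends at the first sample back at/above threshold.
    """
    if sample_period <= 0:
        raise ValueError("sample period must be positive")
    g = np.asarray(glucose, dtype=float)
    count = 0
    run = 0
    for v in g:
        if v < threshold:
            run += 1
        else:
            if run * sample_period >= min_duration:
                count += 1
            run = 0
    if run * sample_period >= min_duration:
        count += 1
    return count


def hypo_event_starts(
    glucose,
    times,
    sample_period: float,
    threshold: float = HYPO_THRESHOLD,
    min_duration: float = HYPO_MIN_DURATION,
) -> list[float]:
    """Start times of qualifying hypoglycemic events."""
    g = np.asarray(glucose, dtype=float)
    t = np.asarray(times, dtype=float)
    starts: list[float] = []
    run = 0
    for i, v in enumerate(g):
        if v < threshold:
            if run == 0:
                start = t[i]
            run += 1
        else:
            if run * sample_period >= min_duration:
                starts.append(start)
            run = 0
    if run * sample_period >= min_duration:
        starts.append(start)
    return starts


def glycemic_excursion(
    trace: pd.DataFrame, meal_time: float, horizon: float = POSTPRANDIAL_HORIZON
) -> float:
    """Maximum BG in [meal_time, meal_time + horizon] minus the premeal BG."""
    t = trace["time_min"].to_numpy()
    if meal_time < t[0] or meal_time + horizon > t[-1]:
        raise ValueError("trace does not cover the postprandial window")
    window = trace[(t >= meal_time) & (t <= meal_time + horizon)]
    premeal = trace.loc[trace["time_min"] == meal_time, "G"].iloc[0]
    return float(window["G"].max() - premeal)


def gmi(mean_glucose: float) -> float:
    """Glucose management indicator (%) from mean CGM glucose (mg/dl)."""
    if mean_glucose < 0:
        raise ValueError("mean glucose must be non-negative")
    return GMI_INTERCEPT + GMI_SLOPE * mean_glucose


def cvga_zone(min_g: float, max_g: float) -> str:
    """CVGA zone for one patient-day from its (min BG, max BG) pair.

    Standard 9-region grid: the minimum-BG axis spans 110 down to 50 with
    category lines at 90 and 70; the maximum-BG axis spans 110 up to 400
    with lines at 180 and 300.  Values are clamped to the plot edges.  The
    zone letter is the sum of the two axis category indices (A + B-shift +
    C-shift ... capped at E).
    """
    if min_g > max_g:
        raise ValueError("need min_g <= max_g")
    lo = min(max(min_g, 50.0), 110.0)
    hi = min(max(max_g, 110.0), 400.0)
    cat_min = 0 if lo >= 90 else (1 if lo >= 70 else 2)
    cat_max = 0 if hi <= 180 else (1 if hi <= 300 else 2)
    return CVGA_ZONES[min(cat_min + cat_max, 4)]


def _is_day(times) -> np.ndarray:
    tod = np.asarray(times, dtype=float) % MIN_PER_DAY
    return (tod >= DAY_START_MIN) & (tod < NIGHT_START_MIN)


def _range_block(g: np.ndarray, prefix: str) -> dict:
    return {
        f"{prefix}mean_glucose": float(np.mean(g)),
        f"{prefix}pct_70_140": time_in_range(g, 70, 140),
        f"{prefix}pct_70_180": time_in_range(g, 70, 180),
        f"{prefix}pct_above_180": time_above(g, 180),
        f"{prefix}pct_below_70": time_below(g, 70),
        f"{prefix}pct_below_54": time_below(g, 54),
        f"{prefix}gmi": gmi(float(np.mean(g))),
    }


def summarize_trace(trace: pd.DataFrame, sample_period: float) -> dict:
    """Per-patient metrics from one simulation trace.

    Meals are located at samples with a positive bolus; excursion and
    postprandial controller insulin are averaged over meals whose full 4-h
    window the trace covers.  Hypoglycemic events are attributed to the
    day/night window containing their start.
    """
    t = trace["time_min"].to_numpy(dtype=float)
    g = trace["G"].to_numpy(dtype=float)
    day = _is_day(t)
    out = _range_block(g, "")
    if day.any():
        out.update(_range_block(g[day], "day_"))
    if (~day).any():
        out.update(_range_block(g[~day], "night_"))

    out["hypo_events"] = hypo_events(g, sample_period)
    starts = hypo_event_starts(g, t, sample_period)
    day_starts = _is_day(starts) if starts else np.array([], dtype=bool)
    out["day_hypo_events"] = int(np.sum(day_starts))
    out["night_hypo_events"] = len(starts) - int(np.sum(day_starts))

    meal_times = trace.loc[trace["bolus"] > 0, "time_min"].to_numpy(dtype=float)
    excursions = []
    pp_insulin = []
    for mt in meal_times:
        if mt + POSTPRANDIAL_HORIZON > t[-1]:
            continue
        excursions.append(glycemic_excursion(trace, mt))
        win = trace[(t > mt) & (t <= mt + POSTPRANDIAL_HORIZON)]
        pp_insulin.append(float((win["u_d"] * sample_period).sum()))
    out["excursion"] = float(np.mean(excursions)) if excursions else float("nan")
    out["postprandial_basal_u"] = float(np.mean(pp_insulin)) if pp_insulin else float("nan")

    zones = cvga_zones_by_day(trace)
    for z in CVGA_ZONES:
        out[f"cvga_pct_{z}"] = 100.0 * zones.count(z) / len(zones) if zones else float("nan")
    return out


def cvga_zones_by_day(trace: pd.DataFrame) -> list[str]:
    """One CVGA zone per complete 24-h block of the trace."""
    t = trace["time_min"].to_numpy(dtype=float)
    g = trace["G"].to_numpy(dtype=float)
    zones = []
    day0 = int(t[0] // MIN_PER_DAY)
    nday = int((t[-1] - t[0] + 1) // MIN_PER_DAY)
    for d in range(day0, day0 + nday):
        mask = (t >= d * MIN_PER_DAY) & (t < (d + 1) * MIN_PER_DAY)
        if mask.any():
            zones.append(cvga_zone(float(g[mask].min()), float(g[mask].max())))
    return zones


def plot_cvga(traces_by_patient: dict[int, pd.DataFrame], path: str, title: str = "CVGA") -> None:
    """Scatter the per-patient-per-day (min BG, max BG) pairs on the CVGA grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for x in (90.0, 70.0):
        ax.axvline(x, color="0.7", lw=0.8)
    for y in (180.0, 300.0):
        ax.axhline(y, color="0.7", lw=0.8)
    for tr in traces_by_patient.values():
        t = tr["time_min"].to_numpy(dtype=float)
        g = tr["G"].to_numpy(dtype=float)
        for d in range(int((t[-1] - t[0] + 1) // MIN_PER_DAY)):
            mask = (t >= d * MIN_PER_DAY) & (t < (d + 1) * MIN_PER_DAY)
            if mask.any():
                lo = min(max(float(g[mask].min()), 50.0), 110.0)
                hi = min(max(float(g[mask].max()), 110.0), 400.0)
                ax.plot(lo, hi, "o", ms=3, color="tab:blue", alpha=0.6)
    ax.set_xlim(110.0, 50.0)  # minimum axis runs right-to-left, as published
    ax.set_ylim(110.0, 400.0)
    ax.set_xlabel("24-h minimum BG (mg/dl)")
    ax.set_ylabel("24-h maximum BG (mg/dl)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class MetricsReport:
    """Cohort metrics per arm.

    per_patient : arm -> DataFrame (one row per patient).
    cohort : arm -> {metric: {"median", "q25", "q75"}} plus summed event
        counts and pooled CVGA zone percentages.
    """

    per_patient: dict[str, pd.DataFrame] = field(default_factory=dict)
    cohort: dict[str, dict] = field(default_factory=dict)
    sample_period: float = 5.0

    def to_dict(self) -> dict:
        return {
            "sample_period": self.sample_period,
            "per_patient": {
                arm: df.to_dict(orient="records") for arm, df in self.per_patient.items()
            },
            "cohort": self.cohort,
        }


def compute_report(
    traces: dict[str, dict[int, pd.DataFrame]], sample_period: float = 5.0
) -> MetricsReport:
    """Aggregate per-patient metrics into a cohort report, one block per arm."""
    report = MetricsReport(sample_period=sample_period)
    for arm, by_patient in traces.items():
        rows = []
        for pid in sorted(by_patient):
            row = summarize_trace(by_patient[pid], sample_period)
            row["patient_id"] = pid
            rows.append(row)
        df = pd.DataFrame(rows).set_index("patient_id")
        report.per_patient[arm] = df
        summary: dict = {}
        for col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            summary[col] = {
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            }
        summary["hypo_events_total"] = int(df["hypo_events"].sum())
        summary["day_hypo_events_total"] = int(df["day_hypo_events"].sum())
        summary["night_hypo_events_total"] = int(df["night_hypo_events"].sum())
        report.cohort[arm] = summary
    return report
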