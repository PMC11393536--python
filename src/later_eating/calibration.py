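"""Definition-selection machinery: half-hour energy profiling, daypart-window
inference, candidate-window comparison and night-eating threshold calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .occasion_builder import DayProfile, Role

__all__ = [
    "N_BINS",
    "BIN_MINUTES",
    "EIProfile",
    "WindowInference",
    "ThresholdDecision",
    "CalibrationError",
    "compute_ei_profile",
    "infer_window_boundaries",
    "compare_candidate_windows",
    "calibrate_ne_threshold",
]

BIN_MINUTES = 30
N_BINS = 1440 // BIN_MINUTES  # 48 half-hour bins covering 00:00-23:59


class CalibrationError(RuntimeError):
    pass


@dataclass
class EIProfile:
    """Cohort mean energy share (% of daily intake) per half-hour bin."""

    values: np.ndarray  # shape (48,)
    n_days: int
    by_day_type: dict[str, np.ndarray] = field(default_factory=dict)
    bedtime_density: np.ndarray | None = None

    def bin_start(self, index: int) -> int:
        return index * BIN_MINUTES


def _day_bin_shares(day: DayProfile) -> np.ndarray | None:
    """Per-bin share of the day's intake, in percent; None if TDEI <= 0.

    Shares use timed energy over timed energy, so they sum to exactly 100 for
    any day with at least one timed occasion (sentinel-time energy has no bin
    to live in).
    """
    timed = sum(o.energy for o in day.occasions)
    if timed <= 0:
        return None
    shares = np.zeros(N_BINS)
    for o in day.occasions:
        shares[o.clock_time // BIN_MINUTES] += o.energy
    return 100.0 * shares / timed


def compute_ei_profile(
    days: Iterable[DayProfile],
    bedtimes_minutes: Sequence[int] | None = None,
) -> EIProfile:
    """Average per-child-day bin shares across the cohort, split by day type."""
    total = np.zeros(N_BINS)
    n = 0
    by_type_sum: dict[str, np.ndarray] = {}
    by_type_n: dict[str, int] = {}
    for day in days:
        shares = _day_bin_shares(day)
        if shares is None:
            continue
        total += shares
        n += 1
        key = day.day_type.value
        by_type_sum.setdefault(key, np.zeros(N_BINS))
        by_type_sum[key] += shares
        by_type_n[key] = by_type_n.get(key, 0) + 1
    if n == 0:
        return EIProfile(values=np.zeros(N_BINS), n_days=0)

    density = None
    if bedtimes_minutes:
        hist = np.zeros(N_BINS)
        for bt in bedtimes_minutes:
            hist[int(bt) // BIN_MINUTES] += 1
        density = hist / hist.sum()

    return EIProfile(
        values=total / n,
        n_days=n,
        by_day_type={k: by_type_sum[k] / by_type_n[k] for k in by_type_sum},
        bedtime_density=density,
    )


@dataclass
class WindowInference:
    daypart_starts: tuple[int, int, int]  # morning, afternoon, evening
    meal_slots: tuple[tuple[int, int], ...]  # usual breakfast/lunch/dinner slots
    peak_bins: tuple[int, int, int]  # argmax bin start minute per peak


def infer_window_boundaries(
    profile: EIProfile,
    epsilon: float = 0.5,
    min_peak_fraction: float = 0.4,
    slot_fraction: float = 0.1,
) -> WindowInference:
    """Place daypart boundaries from the half-hour profile's troughs.

    Bins at or below ``epsilon`` %TDEI form troughs; the contiguous
    above-epsilon segments between them are candidate peaks, and segments
    whose maximum reaches ``min_peak_fraction`` of the global maximum are the
    meal peaks.  Each daypart starts at the first bin of its peak's segment —
    the first bin after the sub-epsilon trough.  Usual mealtime slots are the
    maximal run of bins around each peak above ``slot_fraction`` of that
    peak's height.
    """
    v = profile.values
    if profile.n_days == 0 or v.max() <= epsilon:
        raise CalibrationError("profile is flat; no peaks above epsilon — lower epsilon")

    above = v > epsilon
    segments: list[tuple[int, int]] = []  # [start_bin, end_bin] inclusive
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, N_BINS - 1))

    peak_height = v.max()
    peaks = [(s, e) for s, e in segments if v[s : e + 1].max() >= min_peak_fraction * peak_height]
    if len(peaks) < 3:
        raise CalibrationError(
            f"found {len(peaks)} peak segment(s), need 3 — adjust epsilon or min_peak_fraction"
        )
    peaks = peaks[:3]  # earliest three in time order: breakfast, lunch, dinner

    starts = tuple(s * BIN_MINUTES for s, _ in peaks)
    slots = []
    argmaxes = []
    for s, e in peaks:
        apex = s + int(np.argmax(v[s : e + 1]))
        argmaxes.append(apex * BIN_MINUTES)
        height = v[apex]
        lo = apex
        while lo > s and v[lo - 1] >= slot_fraction * height:
            lo -= 1
        hi = apex
        while hi < e and v[hi + 1] >= slot_fraction * height:
            hi += 1
        slots.append((lo * BIN_MINUTES, hi * BIN_MINUTES + BIN_MINUTES - 1))
    return WindowInference(
        daypart_starts=starts, meal_slots=tuple(slots), peak_bins=tuple(argmaxes)
    )


def _window_energy(day: DayProfile, candidate) -> float | None:
    """Energy in a candidate window; None when undefined for this day."""
    if isinstance(candidate, tuple):
        lo, hi = candidate
        return day.energy_in(lo, hi)
    if candidate == "evening_main_meal":
        main = day.evening_main_meal
        return main.energy if main else 0.0
    if candidate == "evening_snacks":
        return sum(o.energy for o in day.evening_occasions if o.role is Role.SNACK)
    if candidate == "pre_bedtime":
        if day.bedtime is None:
            return None
        return day.energy_in(max(0, day.bedtime - 120), day.bedtime)
    raise ValueError(f"unknown candidate {candidate!r}")


def _per_child_shares(
    days_by_child: Mapping[str, Sequence[DayProfile]], candidate
) -> tuple[np.ndarray, list[list[float]]]:
    """Ratio-of-sums %TDEI per child, plus the per-day shares behind it."""
    child_vals = []
    day_shares: list[list[float]] = []
    for _child, days in sorted(days_by_child.items()):
        num = den = 0.0
        shares = []
        usable = True
        for day in days:
            if day.tdei <= 0:
                usable = False
                break
            e = _window_energy(day, candidate)
            if e is None:
                usable = False
                break
            num += e
            den += day.tdei
            shares.append(100.0 * e / day.tdei)
        if usable and den > 0:
            child_vals.append(100.0 * num / den)
            day_shares.append(shares)
    return np.asarray(child_vals), day_shares


def compare_candidate_windows(
    days_by_child: Mapping[str, Sequence[DayProfile]],
    candidates: Mapping[str, object],
    duplicate_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Quartile summary of per-child %TDEI for each candidate window.

    Candidates map a name to either an inclusive ``(start, end)`` minute tuple
    or one of ``"evening_main_meal"``, ``"evening_snacks"``, ``"pre_bedtime"``.
    Candidates whose (q25, median, q75) all lie within ``duplicate_tolerance``
    of an earlier candidate are flagged as near-duplicates.
    """
    rows = []
    seen: list[tuple[str, np.ndarray]] = []
    for name, cand in candidates.items():
        vals, _ = _per_child_shares(days_by_child, cand)
        if vals.size == 0:
            q = np.array([np.nan] * 3)
        else:
            q = np.percentile(vals, [25, 50, 75])
        dup_of = ""
        for other_name, other_q in seen:
            if np.all(np.abs(q - other_q) <= duplicate_tolerance):
                dup_of = other_name
                break
        seen.append((name, q))
        rows.append(
            {
                "candidate": name,
                "n_children": int(vals.size),
                "q25": q[0],
                "median": q[1],
                "q75": q[2],
                "duplicate_of": dup_of,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ThresholdDecision:
    window: object
    percentile: float
    criterion_pct: float  # rounded energy criterion, % of daily intake
    raw_percentile_value: float
    prevalence_pct: float  # % of children meeting the criterion on >= 1 day
    band: tuple[float, float]
    accepted: bool


def calibrate_ne_threshold(
    days_by_child: Mapping[str, Sequence[DayProfile]],
    window,
    percentile: float = 75.0,
    band: tuple[float, float] = (12.8, 37.0),
    rounding: float = 5.0,
    comparison: str = "ge",
) -> ThresholdDecision:
    """Derive an energy criterion from the cohort's window-share distribution.

    The criterion is the given percentile (linear interpolation) of the
    per-child %TDEI in the window, rounded to the nearest ``rounding`` points;
    prevalence is the share of children meeting it on at least one day, and
    the decision is accepted when prevalence falls inside the reference band.
    """
    child_vals, day_shares = _per_child_shares(days_by_child, window)
    if child_vals.size == 0 or not any(any(s > 0 for s in d) for d in day_shares):
        raise CalibrationError("no usable window intake in the cohort")
    raw = float(np.percentile(child_vals, percentile))
    criterion = float(rounding * round(raw / rounding))
    if comparison == "ge":
        meets = [any(s >= criterion for s in shares) for shares in day_shares]
    else:
        meets = [any(s > criterion for s in shares) for shares in day_shares]
    prevalence = 100.0 * float(np.mean(meets))
    return ThresholdDecision(
        window=window,
        percentile=percentile,
        criterion_pct=criterion,
        raw_percentile_value=raw,
        prevalence_pct=prevalence,
        band=tuple(band),
        accepted=band[0] <= prevalence <= band[1],
    )
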