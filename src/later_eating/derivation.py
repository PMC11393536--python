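"""Per-child derivation of the 13 later-eating-rhythm variables.

Variables fall into three groups, computed per day-type stratum (whole week,
weekdays only, weekend days only):

timing
    T1a/T1b  days with any occasion after the individual / cohort-average
             bedtime (strictly after, same calendar day)
    T2       mean time of the evening main meal (minutes)
    T3       mean time of the last occasion of the day (minutes)
energy (percent of total daily energy intake, ratio of sums across days)
    E1a      evening window
    E1b      the two hours up to and including bedtime
    E2 / E3  evening main meal / evening snacks (E2 + E3 == E1a exactly)
    E1c1     days with >= 30 %TDEI after 18:00 (per-day denominator)
    E1c2     days with >= 25 %TDEI within 2 h before bedtime
frequency
    F1       median daily count of evening occasions
    F2       days with an occasion in the usual dinner slot
    F3       days with an evening occasion strictly after the evening main meal

%TDEI aggregation is a ratio of sums (sum of window energy over the stratum's
days divided by the sum of those days' TDEIs), not a mean of daily ratios.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd

from .config import StudyConfig
from .diary_io import BedtimeRecord, DayType, FoodRecord
from .occasion_builder import DayProfile, Role, build_day_profile

__all__ = [
    "Stratum",
    "LERProfile",
    "VARIABLE_NAMES",
    "stratify_days",
    "derive_timing",
    "derive_energy",
    "derive_night_eating",
    "derive_frequency",
    "derive_profile",
    "derive_all",
    "build_day_profiles",
    "bin_day_count",
    "profiles_to_frame",
]

VARIABLE_NAMES = (
    "T1a", "T1b", "T2", "T3",
    "E1a", "E1b", "E1c1", "E1c2", "E2", "E3",
    "F1", "F2", "F3",
)


class Stratum(str, enum.Enum):
    WHOLE_WEEK = "whole_week"
    WEEKDAYS = "weekdays"
    WEEKEND = "weekend"


@dataclass
class LERProfile:
    """The 13 derived variables for one child in one stratum (None = missing)."""

    child_id: str
    stratum: Stratum
    n_days: int
    T1a: int | None = None
    T1b: int | None = None
    T2: float | None = None
    T3: float | None = None
    E1a: float | None = None
    E1b: float | None = None
    E1c1: int | None = None
    E1c2: int | None = None
    E2: float | None = None
    E3: float | None = None
    F1: float | None = None
    F2: int | None = None
    F3: int | None = None
    flags: list[str] = field(default_factory=list)


def stratify_days(days: Sequence[DayProfile]) -> dict[Stratum, list[DayProfile]]:
    """Assign a child's recorded days to the strata they qualify for.

    Whole week requires exactly three recorded days (any weekday/weekend mix,
    including three weekdays); weekdays requires at least two weekday days and
    uses only those; weekend requires at least one weekend day.
    """
    days = sorted(days, key=lambda d: d.day_index)
    weekday_days = [d for d in days if d.day_type is DayType.WEEKDAY]
    weekend_days = [d for d in days if d.day_type is DayType.WEEKEND]
    out: dict[Stratum, list[DayProfile]] = {}
    if len(days) == 3:
        out[Stratum.WHOLE_WEEK] = list(days)
    if len(weekday_days) >= 2:
        out[Stratum.WEEKDAYS] = weekday_days
    if len(weekend_days) >= 1:
        out[Stratum.WEEKEND] = weekend_days
    return out


def _individual_bedtime(day: DayProfile, bedtime: BedtimeRecord | None) -> int | None:
    if bedtime is None:
        return None
    return bedtime.for_day_type(day.day_type)


def derive_timing(
    days: Sequence[DayProfile],
    bedtime: BedtimeRecord | None,
    config: StudyConfig,
) -> dict[str, float | int | None]:
    """T1a, T1b (day counts) and T2, T3 (mean minutes)."""
    t1a: int | None = 0
    for day in days:
        bt = _individual_bedtime(day, bedtime)
        if bt is None:
            t1a = None  # missing bedtime: child drops out of T1a
            break
        if any(o.clock_time > bt for o in day.occasions):
            t1a += 1

    t1b = sum(
        1
        for day in days
        if any(o.clock_time > config.average_bedtime(day.day_type) for o in day.occasions)
    )

    main_times = [d.evening_main_meal.clock_time for d in days if d.evening_main_meal]
    t2 = statistics.fmean(main_times) if main_times else None
    last_times = [d.last_occasion.clock_time for d in days if d.last_occasion]
    t3 = statistics.fmean(last_times) if last_times else None
    return {"T1a": t1a, "T1b": t1b, "T2": t2, "T3": t3}


def _pre_bedtime_energy(day: DayProfile, bt: int, config: StudyConfig) -> float:
    return day.energy_in(max(0, bt - config.ne_bedtime_window), bt)


def derive_energy(
    days: Sequence[DayProfile],
    bedtime: BedtimeRecord | None,
    config: StudyConfig,
) -> dict[str, float | None]:
    """E1a, E1b, E2, E3 as percent of TDEI, aggregated ratio-of-sums."""
    if any(day.tdei <= 0 for day in days):
        return {"E1a": None, "E1b": None, "E2": None, "E3": None}
    tdei_total = sum(day.tdei for day in days)

    evening = sum(d.energy_in(config.evening_start, 1439) for d in days)
    e2_kcal = sum(
        o.energy for d in days for o in d.evening_occasions if o.role is Role.MAIN_MEAL
    )
    e3_kcal = sum(
        o.energy for d in days for o in d.evening_occasions if o.role is Role.SNACK
    )

    e1b: float | None
    pre_bed = 0.0
    e1b_defined = True
    for day in days:
        bt = _individual_bedtime(day, bedtime)
        if bt is None:
            e1b_defined = False
            break
        pre_bed += _pre_bedtime_energy(day, bt, config)
    e1b = 100.0 * pre_bed / tdei_total if e1b_defined else None

    return {
        "E1a": 100.0 * evening / tdei_total,
        "E1b": e1b,
        "E2": 100.0 * e2_kcal / tdei_total,
        "E3": 100.0 * e3_kcal / tdei_total,
    }


def derive_night_eating(
    days: Sequence[DayProfile],
    bedtime: BedtimeRecord | None,
    config: StudyConfig,
) -> dict[str, int | None]:
    """E1c1, E1c2: per-day classification against that day's own TDEI."""
    if any(day.tdei <= 0 for day in days):
        return {"E1c1": None, "E1c2": None}

    e1c1 = sum(
        1
        for day in days
        if config.ne_meets(
            100.0 * day.energy_in(config.ne_clock_threshold, 1439) / day.tdei,
            config.ne_clock_criterion_pct,
        )
    )

    e1c2: int | None = 0
    for day in days:
        bt = _individual_bedtime(day, bedtime)
        if bt is None:
            e1c2 = None
            break
        share = 100.0 * _pre_bedtime_energy(day, bt, config) / day.tdei
        if config.ne_meets(share, config.ne_bedtime_criterion_pct):
            e1c2 += 1
    return {"E1c1": e1c1, "E1c2": e1c2}


def derive_frequency(
    days: Sequence[DayProfile], config: StudyConfig
) -> dict[str, float | int]:
    """F1 (median evening occasions per day), F2 and F3 (day counts)."""
    counts = [len(d.evening_occasions) for d in days]
    f1 = statistics.median(counts)
    lo, hi = config.dinner_slot
    f2 = sum(1 for d in days if any(lo <= o.clock_time <= hi for o in d.occasions))
    f3 = 0
    for d in days:
        main = d.evening_main_meal
        if main and any(o.clock_time > main.clock_time for o in d.evening_occasions):
            f3 += 1
    return {"F1": f1, "F2": f2, "F3": f3}


def derive_profile(
    child_id: str,
    days: Sequence[DayProfile],
    stratum: Stratum,
    bedtime: BedtimeRecord | None,
    config: StudyConfig,
) -> LERProfile:
    """Derive all 13 variables for one child in one stratum."""
    values: dict = {}
    values.update(derive_timing(days, bedtime, config))
    values.update(derive_energy(days, bedtime, config))
    values.update(derive_night_eating(days, bedtime, config))
    values.update(derive_frequency(days, config))
    profile = LERProfile(child_id=child_id, stratum=stratum, n_days=len(days), **values)
    if profile.E1a is None:
        profile.flags.append("zero_tdei_day")
    if profile.T1a is None:
        profile.flags.append("missing_bedtime")
    return profile


def build_day_profiles(
    records: Iterable[FoodRecord],
    bedtimes: Iterable[BedtimeRecord],
    config: StudyConfig,
) -> tuple[dict[str, list[DayProfile]], dict[str, BedtimeRecord]]:
    """Group a cohort's records into per-child day profiles.

    The day-type individual bedtime is attached to each day profile (used for
    bedtime-relative windows downstream).
    """
    bedtime_by_child = {b.child_id: b for b in bedtimes}
    by_day: dict[tuple[str, int], list[FoodRecord]] = {}
    for r in records:
        by_day.setdefault((r.child_id, r.day_index), []).append(r)

    days_by_child: dict[str, list[DayProfile]] = {}
    for (child_id, _day_index), recs in sorted(by_day.items()):
        bed = bedtime_by_child.get(child_id)
        bt = bed.for_day_type(recs[0].day_type) if bed else None
        days_by_child.setdefault(child_id, []).append(
            build_day_profile(recs, config, bedtime=bt)
        )
    return days_by_child, bedtime_by_child


def derive_all(
    records: Iterable[FoodRecord],
    bedtimes: Iterable[BedtimeRecord],
    config: StudyConfig | None = None,
) -> tuple[list[LERProfile], list[tuple[str, str]]]:
    """Derive profiles for every child and every stratum they qualify for.

    Returns ``(profiles, issues)``; issues is a list of (child_id, reason)
    covering excluded strata and per-child derivation problems — children are
    never dropped silently.
    """
    config = config or StudyConfig()
    days_by_child, bedtime_by_child = build_day_profiles(records, bedtimes, config)

    profiles: list[LERProfile] = []
    issues: list[tuple[str, str]] = []
    for child_id, days in days_by_child.items():
        strata = stratify_days(days)
        if Stratum.WHOLE_WEEK not in strata:
            issues.append((child_id, f"not whole-week eligible ({len(days)} recorded days)"))
        for stratum, member_days in strata.items():
            profile = derive_profile(
                child_id, member_days, stratum, bedtime_by_child.get(child_id), config
            )
            profiles.append(profile)
            for flag in profile.flags:
                issues.append((child_id, f"{stratum.value}: {flag}"))
    return profiles, issues


# Per-stratum day-count bins for the categorical variables.
_BINS = {
    Stratum.WHOLE_WEEK: ("0", "1", "2", "3"),
    Stratum.WEEKDAYS: ("0", "1", ">=2"),
    Stratum.WEEKEND: ("0", ">=1"),
}


def bin_day_count(count: int | None, stratum: Stratum) -> str | None:
    """Map a raw day count to its stratum's category label."""
    if count is None:
        return None
    labels = _BINS[stratum]
    top = len(labels) - 1
    if count >= top:
        return labels[top]
    return labels[count]


def profiles_to_frame(profiles: Iterable[LERProfile]) -> pd.DataFrame:
    """One row per child x stratum, columns T1a..F3 plus n_days and flags."""
    rows = []
    for p in profiles:
        row = {
            f.name: getattr(p, f.name)
            for f in fields(LERProfile)
            if f.name not in ("flags", "stratum")
        }
        row["stratum"] = p.stratum.value
        row["flags"] = ";".join(p.flags)
        rows.append(row)
    columns = ["child_id", "stratum", "n_days", *VARIABLE_NAMES, "flags"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(["stratum", "child_id"], kind="stable").reset_index(drop=True)
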