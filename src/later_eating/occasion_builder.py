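"""Eating occasions and day profiles.

An eating occasion is the set of records sharing one recorded clock time on a
day; within each of the morning/afternoon/evening windows the largest-energy
occasion is the main meal (earliest wins a tie) and everything else is a
snack.  Records before the morning window ("first thing") count toward daily
energy but are never main meals.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

from .config import StudyConfig
from .diary_io import DayType, FoodRecord, SentinelTime

__all__ = [
    "Daypart",
    "Role",
    "EatingOccasion",
    "DayProfile",
    "build_occasions",
    "classify_roles",
    "detect_meal_skipping",
    "build_day_profile",
]


class Daypart(str, enum.Enum):
    FIRST_THING = "first_thing"
    MORNING = "morning"
    AFTERNOON = "afternoon"
    EVENING = "evening"


class Role(str, enum.Enum):
    MAIN_MEAL = "main_meal"
    SNACK = "snack"


MEAL_DAYPARTS = (Daypart.MORNING, Daypart.AFTERNOON, Daypart.EVENING)


@dataclass
class EatingOccasion:
    child_id: str
    day_index: int
    clock_time: int
    energy: float
    daypart: Daypart | None = None
    role: Role | None = None

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError("occasion energy must be non-negative")


def daypart_of(clock_time: int, config: StudyConfig) -> Daypart:
    if clock_time < config.morning_start:
        return Daypart.FIRST_THING
    if clock_time < config.afternoon_start:
        return Daypart.MORNING
    if clock_time < config.evening_start:
        return Daypart.AFTERNOON
    return Daypart.EVENING


def build_occasions(records: Sequence[FoodRecord]) -> list[EatingOccasion]:
    """Group one child-day's records into occasions by recorded time.

    One occasion per distinct non-sentinel clock time, energy summed across its
    records, sorted ascending by time.  Sentinel-time records contribute no
    occasion; an all-sentinel day yields an empty list with a warning.
    """
    if not records:
        return []
    keys = {(r.child_id, r.day_index) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple child-days: {sorted(keys)}")
    (child_id, day_index), = keys

    timed = sorted((r for r in records if r.has_time), key=lambda r: r.clock_time)
    if not timed:
        warnings.warn(
            f"{child_id}/day{day_index}: all records have sentinel times; no occasions",
            stacklevel=2,
        )
        return []
    return [
        EatingOccasion(
            child_id=child_id,
            day_index=day_index,
            clock_time=t,
            energy=sum(r.energy for r in group),
        )
        for t, group in groupby(timed, key=lambda r: r.clock_time)
    ]


def classify_roles(
    occasions: Iterable[EatingOccasion], config: StudyConfig
) -> list[EatingOccasion]:
    """Assign daypart and main-meal/snack role; canonical time order.

    The largest-energy occasion within each meal daypart is the main meal
    (ties broken by earliest time); all other occasions, and everything in the
    first-thing window, are snacks.
    """
    out = sorted(occasions, key=lambda o: o.clock_time)
    for occ in out:
        occ.daypart = daypart_of(occ.clock_time, config)
        occ.role = Role.SNACK
    for part in MEAL_DAYPARTS:
        members = [o for o in out if o.daypart is part]
        if members:
            main = max(members, key=lambda o: (o.energy, -o.clock_time))
            main.role = Role.MAIN_MEAL
    return out


def detect_meal_skipping(
    occasions: Sequence[EatingOccasion], config: StudyConfig
) -> dict[str, bool]:
    """Skip flags: no occasion at all inside the usual mealtime slot."""
    slots = {
        "breakfast": config.breakfast_slot,
        "lunch": config.lunch_slot,
        "dinner": config.dinner_slot,
    }
    return {
        meal: not any(lo <= o.clock_time <= hi for o in occasions)
        for meal, (lo, hi) in slots.items()
    }


@dataclass
class DayProfile:
    """One recorded child-day: occasions, total energy and derived flags."""

    child_id: str
    day_index: int
    day_type: DayType
    tdei: float
    occasions: list[EatingOccasion]
    sentinel_energy: float = 0.0
    daypart_energy: dict[Daypart, float] = field(default_factory=dict)
    skipped: dict[str, bool] = field(default_factory=dict)
    bedtime: int | None = None

    @property
    def evening_occasions(self) -> list[EatingOccasion]:
        return [o for o in self.occasions if o.daypart is Daypart.EVENING]

    @property
    def evening_main_meal(self) -> EatingOccasion | None:
        for o in self.evening_occasions:
            if o.role is Role.MAIN_MEAL:
                return o
        return None

    @property
    def last_occasion(self) -> EatingOccasion | None:
        return self.occasions[-1] if self.occasions else None

    def energy_in(self, start: int, end: int) -> float:
        """Summed occasion energy with clock time in [start, end] inclusive."""
        return sum(o.energy for o in self.occasions if start <= o.clock_time <= end)


def build_day_profile(
    records: Sequence[FoodRecord],
    config: StudyConfig,
    bedtime: int | None = None,
) -> DayProfile:
    """Assemble a full day profile for one child-day.

    TDEI is the sum of occasion energies, plus sentinel-record energy when the
    configured policy includes it.
    """
    if not records:
        raise ValueError("cannot build a day profile from zero records")
    keys = {(r.child_id, r.day_index, r.day_type) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple child-days: {sorted(keys)}")
    (child_id, day_index, day_type), = keys

    occasions = classify_roles(build_occasions(records), config)
    sentinel_energy = sum(
        r.energy for r in records if isinstance(r.clock_time, SentinelTime)
    )
    tdei = sum(o.energy for o in occasions)
    if config.sentinel_energy_policy == "include_in_tdei":
        tdei += sentinel_energy
    daypart_energy = {part: 0.0 for part in Daypart}
    for o in occasions:
        daypart_energy[o.daypart] += o.energy
    return DayProfile(
        child_id=child_id,
        day_index=day_index,
        day_type=day_type,
        tdei=tdei,
        occasions=occasions,
        sentinel_energy=sentinel_energy,
        daypart_energy=daypart_energy,
        skipped=detect_meal_skipping(occasions, config),
        bedtime=bedtime,
    )
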