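"""Synthetic diary + bedtime cohorts with the structure the analysis assumes.

Each child records up to three days (default two weekdays and one weekend
day).  Occasion times follow a trimodal pattern — breakfast, lunch and dinner
drawn from truncated normals inside their daypart windows (with a small
uniform admixture so window edges carry mass), optional snacks between meals —
which leaves near-zero troughs before 06:00, before 12:00 and before 17:00 in
the half-hour energy profile.  Per-occasion energy shares are Dirichlet draws
around per-child shares, so both between- and within-child variability are
controlled; daily energy is the exact sum of occasion energies.

A truth table (one row per generated child-day) records evening energy share,
last-occasion time and the other quantities the derivation pipeline should
recover, enabling parameter-recovery tests without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .diary_io import BedtimeRecord, DayType, FoodRecord, SentinelTime, code_meal_slot

__all__ = ["GeneratorParams", "ParameterError", "CohortData", "generate_cohort", "degrade_to_slots"]


class ParameterError(ValueError):
    """An invalid generator parameter; names the offending field."""


OCCASION_TYPES = (
    "breakfast",
    "morning_snack",
    "lunch",
    "afternoon_snack",
    "dinner",
    "evening_snack",
)


@dataclass(frozen=True)
class GeneratorParams:
    n_children: int = 100
    seed: int = 0

    # main meal timing: truncated normal inside each window plus a uniform
    # admixture over the window (keeps mass near window edges)
    meal_time_means: tuple[float, float, float] = (480.0, 765.0, 1065.0)
    meal_time_sds: tuple[float, float, float] = (30.0, 30.0, 30.0)
    meal_time_windows: tuple[tuple[int, int], ...] = ((360, 599), (720, 899), (1020, 1260))
    uniform_mix: float = 0.10

    # snack timing: morning/afternoon snacks uniform in their windows; the
    # evening snack lands a random offset after dinner
    snack_windows: tuple[tuple[int, int], tuple[int, int]] = ((600, 659), (900, 989))
    evening_snack_offset: tuple[int, int] = (30, 210)
    snack_probabilities: tuple[float, float, float] = (0.6, 0.7, 0.7)

    # mean energy share per occasion type (order OCCASION_TYPES); must sum to 1
    energy_shares: tuple[float, ...] = (0.19, 0.09, 0.24, 0.12, 0.28, 0.08)
    # Dirichlet concentrations: child-level spread and day-level (within-child)
    share_concentration_child: float = 150.0
    share_concentration_day: float = 350.0

    tdei_mean: float = 1600.0
    tdei_sd: float = 250.0
    tdei_min: float = 600.0

    bedtime_means: tuple[float, float] = (1203.0, 1242.0)  # weekday, weekend
    bedtime_sd: float = 25.0

    p_missing_bedtime: float = 0.02
    p_incomplete_days: float = 0.0
    p_no_time: float = 0.0  # per-record chance of sentinel code 99
    p_unmatched: float = 0.0  # per-day chance of one extra code-88 row
    day_type_pattern: tuple[str, str, str] = ("weekday", "weekday", "weekend")

    def validate(self) -> None:
        if self.n_children <= 0:
            raise ParameterError("n_children must be positive")
        for name in (
            "uniform_mix", "p_missing_bedtime", "p_incomplete_days",
            "p_no_time", "p_unmatched",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for p in self.snack_probabilities:
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"snack_probabilities entries must lie in [0, 1], got {p}")
        for name in ("meal_time_sds",):
            if any(s <= 0 for s in getattr(self, name)):
                raise ParameterError(f"{name} entries must be positive")
        if len(self.energy_shares) != len(OCCASION_TYPES):
            raise ParameterError("energy_shares must have one entry per occasion type")
        if any(s <= 0 for s in self.energy_shares):
            raise ParameterError("energy_shares entries must be positive")
        if abs(sum(self.energy_shares) - 1.0) > 1e-9:
            raise ParameterError("energy_shares must sum to 1")
        if self.share_concentration_child <= 0 or self.share_concentration_day <= 0:
            raise ParameterError("share concentrations must be positive")
        if self.tdei_sd <= 0 or self.bedtime_sd <= 0:
            raise ParameterError("tdei_sd and bedtime_sd must be positive")
        for day_type in self.day_type_pattern:
            if day_type not in ("weekday", "weekend"):
                raise ParameterError(f"day_type_pattern entries must be weekday/weekend, got {day_type!r}")
        for lo, hi in (*self.meal_time_windows, *self.snack_windows):
            if not 0 <= lo < hi <= 1439:
                raise ParameterError(f"time window ({lo}, {hi}) must be ordered inside [0, 1439]")

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


class CohortData(NamedTuple):
    records: list[FoodRecord]
    bedtimes: list[BedtimeRecord]
    truth: pd.DataFrame
    params: GeneratorParams


def _draw_meal_time(rng: np.random.Generator, mean: float, sd: float,
                    window: tuple[int, int], uniform_mix: float) -> int:
    lo, hi = window
    if rng.random() < uniform_mix:
        return int(rng.integers(lo, hi + 1))
    for _ in range(1000):
        t = rng.normal(mean, sd)
        if lo <= t <= hi:
            return int(round(t))
    return int(np.clip(round(mean), lo, hi))  # pathological mean/window combos


def _day_truth(child_id: str, day_index: int, day_type: str,
               records: list[FoodRecord], bedtime: int | None) -> dict:
    """True per-day quantities, computed from the final record set by the same
    grouping rule the pipeline applies (records sharing a time merge)."""
    timed: dict[int, float] = {}
    tdei = 0.0
    for r in records:
        tdei += r.energy
        if r.has_time:
            timed[r.clock_time] = timed.get(r.clock_time, 0.0) + r.energy
    times = sorted(timed)
    evening = [t for t in times if t >= 1020]
    evening_kcal = sum(timed[t] for t in evening)
    after_1800 = sum(timed[t] for t in times if t >= 1080)
    main_time = None
    if evening:
        main_time = max(evening, key=lambda t: (timed[t], -t))
    return {
        "child_id": child_id,
        "day_index": day_index,
        "day_type": day_type,
        "tdei": tdei,
        "evening_kcal": evening_kcal,
        "evening_share_pct": 100.0 * evening_kcal / tdei if tdei > 0 else np.nan,
        "after_1800_share_pct": 100.0 * after_1800 / tdei if tdei > 0 else np.nan,
        "last_time": times[-1] if times else np.nan,
        "evening_main_time": main_time if main_time is not None else np.nan,
        "n_evening_occasions": len(evening),
        "bedtime": bedtime if bedtime is not None else np.nan,
        "ate_after_bedtime": bool(times and bedtime is not None and times[-1] > bedtime),
    }


def generate_cohort(params: GeneratorParams) -> CohortData:
    """Generate a seeded cohort of diary records, bedtimes and truth.

    Deterministic for a fixed seed.  Energy values are rounded to 0.1 kcal so
    CSV round-trips are exact; per-day TDEI is by construction the exact sum
    of the day's record energies.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    base_shares = np.asarray(params.energy_shares)

    records: list[FoodRecord] = []
    bedtimes: list[BedtimeRecord] = []
    truth_rows: list[dict] = []

    for i in range(params.n_children):
        child_id = f"c{i + 1:05d}"

        wd_bed = int(round(np.clip(rng.normal(params.bedtime_means[0], params.bedtime_sd), 0, 1439)))
        we_bed = int(round(np.clip(rng.normal(params.bedtime_means[1], params.bedtime_sd), 0, 1439)))
        bed_missing = rng.random() < params.p_missing_bedtime
        bedtimes.append(
            BedtimeRecord(
                child_id=child_id,
                weekday_bedtime=None if bed_missing else wd_bed,
                weekend_bedtime=None if bed_missing else we_bed,
            )
        )

        child_shares = rng.dirichlet(base_shares * params.share_concentration_child)

        n_days = len(params.day_type_pattern)
        if params.p_incomplete_days > 0 and rng.random() < params.p_incomplete_days:
            n_days = int(rng.integers(1, len(params.day_type_pattern)))

        for day_index, day_type in enumerate(params.day_type_pattern[:n_days], start=1):
            day_shares = rng.dirichlet(
                np.maximum(child_shares, 1e-6) * params.share_concentration_day
            )

            present = [True, rng.random() < params.snack_probabilities[0],
                       True, rng.random() < params.snack_probabilities[1],
                       True, rng.random() < params.snack_probabilities[2]]
            shares = np.where(present, day_shares, 0.0)
            shares = shares / shares.sum()

            times: dict[str, int] = {}
            for j, name in enumerate(("breakfast", "lunch", "dinner")):
                times[name] = _draw_meal_time(
                    rng,
                    params.meal_time_means[j],
                    params.meal_time_sds[j],
                    params.meal_time_windows[j],
                    params.uniform_mix,
                )
            if present[1]:
                lo, hi = params.snack_windows[0]
                times["morning_snack"] = int(rng.integers(lo, hi + 1))
            if present[3]:
                lo, hi = params.snack_windows[1]
                times["afternoon_snack"] = int(rng.integers(lo, hi + 1))
            if present[5]:
                lo, hi = params.evening_snack_offset
                times["evening_snack"] = min(1439, times["dinner"] + int(rng.integers(lo, hi + 1)))

            tdei = max(params.tdei_min, rng.normal(params.tdei_mean, params.tdei_sd))
            day_records: list[FoodRecord] = []
            for j, name in enumerate(OCCASION_TYPES):
                if name not in times:
                    continue
                energy = round(float(shares[j] * tdei), 1)
                clock: int | SentinelTime = times[name]
                if params.p_no_time > 0 and rng.random() < params.p_no_time:
                    clock = SentinelTime.NO_TIME
                day_records.append(
                    FoodRecord(
                        child_id=child_id,
                        day_index=day_index,
                        day_type=DayType(day_type),
                        clock_time=clock,
                        energy=energy,
                        label=name,
                    )
                )
            if params.p_unmatched > 0 and rng.random() < params.p_unmatched:
                day_records.append(
                    FoodRecord(
                        child_id=child_id,
                        day_index=day_index,
                        day_type=DayType(day_type),
                        clock_time=SentinelTime.UNMATCHED,
                        energy=round(float(rng.uniform(10, 60)), 1),
                        label="unmatched_db_item",
                    )
                )
            records.extend(day_records)
            bed = None if bed_missing else (wd_bed if day_type == "weekday" else we_bed)
            truth_rows.append(_day_truth(child_id, day_index, day_type, day_records, bed))

    truth = pd.DataFrame(truth_rows)
    return CohortData(records=records, bedtimes=bedtimes, truth=truth, params=params)


def degrade_to_slots(records: list[FoodRecord]) -> list[FoodRecord]:
    """Replace each exact time with its historical coarse meal-slot code.

    Models the pre-exact-time database; idempotent, and requires all records
    to carry a real time.
    """
    out = []
    for r in records:
        if not r.has_time:
            raise ValueError("cannot degrade sentinel-time records to slots")
        _, coded = code_meal_slot(r.clock_time)
        out.append(replace(r, clock_time=coded))
    return out
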