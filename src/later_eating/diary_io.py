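"""Reading, validation and historical re-coding of food-diary and bedtime tables.

Diary CSVs are long-format: one row per timed food/drink record with columns
``child_id, day_index, day_type, time, energy_kcal`` and an optional ``label``.
Times are accepted as ``HH:MM`` or four-digit ``HHMM`` and stored internally as
integer minutes since midnight; the raw codes ``99`` (food present, no recorded
time) and ``88`` (database food not matched in the diary) map to sentinels and
are retained, not dropped — downstream policy decides what to do with their
energy.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "DayType",
    "SentinelTime",
    "ClockTime",
    "FoodRecord",
    "BedtimeRecord",
    "ValidationReport",
    "DiaryFormatError",
    "DiaryRowError",
    "MEAL_SLOTS",
    "parse_clock_time",
    "format_clock_time",
    "code_meal_slot",
    "read_diary",
    "write_diary",
    "read_bedtimes",
    "write_bedtimes",
    "validate_cohort",
]

MINUTES_PER_DAY = 1440


class DayType(str, enum.Enum):
    WEEKDAY = "weekday"
    WEEKEND = "weekend"


class SentinelTime(enum.Enum):
    """Raw diary time codes that carry no clock time."""

    NO_TIME = 99  # food found in diary, no time of consumption recorded
    UNMATCHED = 88  # food in database not found in the paper diary

    def __str__(self) -> str:  # serialised back to the raw code
        return str(self.value)


ClockTime = Union[int, SentinelTime]


class DiaryFormatError(ValueError):
    """A diary/bedtime file is structurally unusable (e.g. missing column)."""


class DiaryRowError(ValueError):
    """A single row failed to parse; carries the 1-based data row number."""

    def __init__(self, row_number: int, message: str):
        super().__init__(f"row {row_number}: {message}")
        self.row_number = row_number


def parse_clock_time(text: str) -> ClockTime:
    """Parse ``HH:MM`` or 3/4-digit ``HHMM`` into minutes since midnight.

    The raw codes ``99`` and ``88`` return sentinels.  Anything else that does
    not denote a time in ``[00:00, 23:59]`` raises ``ValueError``.
    """
    raw = text.strip()
    if raw == "99":
        return SentinelTime.NO_TIME
    if raw == "88":
        return SentinelTime.UNMATCHED
    if ":" in raw:
        hh, _, mm = raw.partition(":")
    elif raw.isdigit() and 3 <= len(raw) <= 4:
        hh, mm = raw[:-2], raw[-2:]
    else:
        raise ValueError(f"unrecognised time {text!r}")
    if not (hh.isdigit() and mm.isdigit()):
        raise ValueError(f"unrecognised time {text!r}")
    hours, minutes = int(hh), int(mm)
    if not (0 <= hours <= 23 and 0 <= minutes <= 59):
        raise ValueError(f"time {text!r} outside 00:00-23:59")
    return hours * 60 + minutes


def format_clock_time(t: ClockTime) -> str:
    if isinstance(t, SentinelTime):
        return str(t.value)
    return f"{t // 60:02d}:{t % 60:02d}"


@dataclass(frozen=True)
class FoodRecord:
    """One timed intake row: a single food/drink on one recorded day."""

    child_id: str
    day_index: int
    day_type: DayType
    clock_time: ClockTime
    energy: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.day_index not in (1, 2, 3):
            raise ValueError(f"day_index must be 1-3, got {self.day_index}")
        if not isinstance(self.clock_time, SentinelTime):
            if not 0 <= self.clock_time < MINUTES_PER_DAY:
                raise ValueError(f"clock_time {self.clock_time} outside [0, 1439]")
        if self.energy < 0:
            raise ValueError(f"energy must be non-negative, got {self.energy}")

    @property
    def has_time(self) -> bool:
        return not isinstance(self.clock_time, SentinelTime)


@dataclass(frozen=True)
class BedtimeRecord:
    """Usual bedtimes (minutes since midnight) for one child, per day type."""

    child_id: str
    weekday_bedtime: int | None
    weekend_bedtime: int | None
    source: str = "individual"  # or "population_average"

    def __post_init__(self) -> None:
        for name in ("weekday_bedtime", "weekend_bedtime"):
            v = getattr(self, name)
            if v is not None and not 0 <= v < MINUTES_PER_DAY:
                raise ValueError(f"{name} {v} outside [0, 1439]")

    def for_day_type(self, day_type: DayType) -> int | None:
        if day_type is DayType.WEEKDAY:
            return self.weekday_bedtime
        return self.weekend_bedtime


# Historical coarse meal-slot coding: (first minute, last minute, label, coded
# minutes).  The seven intervals partition [0, 1439]; printed endpoints are
# inclusive.
MEAL_SLOTS: tuple[tuple[int, int, str, int], ...] = (
    (0, 419, "first_thing", 360),
    (420, 599, "breakfast", 480),
    (600, 719, "mid_morning", 660),
    (720, 869, "lunch", 780),
    (870, 1019, "tea", 1020),
    (1020, 1169, "evening_meal", 1200),
    (1170, 1439, "late_evening", 1320),
)


def code_meal_slot(clock_time: int) -> tuple[str, int]:
    """Map an exact time to its coarse meal-slot label and coded time.

    Returns e.g. ``("breakfast", 480)`` for 08:15 — the slot a pre-exact-time
    database would have stored.  Sentinel inputs cannot be coded.
    """
    if isinstance(clock_time, SentinelTime):
        raise ValueError("cannot code a sentinel time to a meal slot")
    if not 0 <= clock_time < MINUTES_PER_DAY:
        raise ValueError(f"clock_time {clock_time} outside [0, 1439]")
    for lo, hi, label, coded in MEAL_SLOTS:
        if lo <= clock_time <= hi:
            return label, coded
    raise AssertionError("unreachable: slots partition the day")


_DIARY_COLUMNS = ("child_id", "day_index", "day_type", "time", "energy_kcal")


def read_diary(path: str | Path) -> list[FoodRecord]:
    """Read a long-format diary CSV into records.

    Raises ``DiaryFormatError`` for a missing required column and
    ``DiaryRowError`` (with the data row number) for unparseable rows.
    """
    path = Path(path)
    records: list[FoodRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _DIARY_COLUMNS:
            if col not in header:
                raise DiaryFormatError(f"diary file {path} missing column {col!r}")
        for i, row in enumerate(reader, start=1):
            try:
                clock = parse_clock_time(row["time"])
                day_type = DayType(row["day_type"].strip().lower())
                label = (row.get("label") or "").strip() or None
                records.append(
                    FoodRecord(
                        child_id=row["child_id"].strip(),
                        day_index=int(row["day_index"]),
                        day_type=day_type,
                        clock_time=clock,
                        energy=float(row["energy_kcal"]),
                        label=label,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise DiaryRowError(i, str(exc)) from exc
    return records


def write_diary(records: Iterable[FoodRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DIARY_COLUMNS + ("label",))
        for r in records:
            writer.writerow(
                [
                    r.child_id,
                    r.day_index,
                    r.day_type.value,
                    format_clock_time(r.clock_time),
                    repr(r.energy) if isinstance(r.energy, float) else r.energy,
                    r.label or "",
                ]
            )


_BEDTIME_COLUMNS = ("child_id", "weekday_bedtime", "weekend_bedtime")


def read_bedtimes(path: str | Path) -> list[BedtimeRecord]:
    """Read a per-child bedtime CSV; blank cells are missing bedtimes."""
    path = Path(path)
    out: list[BedtimeRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _BEDTIME_COLUMNS:
            if col not in header:
                raise DiaryFormatError(f"bedtime file {path} missing column {col!r}")
        for i, row in enumerate(reader, start=1):
            try:
                def _parse(cell: str) -> int | None:
                    cell = cell.strip()
                    if not cell:
                        return None
                    t = parse_clock_time(cell)
                    if isinstance(t, SentinelTime):
                        raise ValueError(f"sentinel {cell!r} not allowed as bedtime")
                    return t

                out.append(
                    BedtimeRecord(
                        child_id=row["child_id"].strip(),
                        weekday_bedtime=_parse(row["weekday_bedtime"]),
                        weekend_bedtime=_parse(row["weekend_bedtime"]),
                        source=(row.get("source") or "individual").strip(),
                    )
                )
            except ValueError as exc:
                raise DiaryRowError(i, str(exc)) from exc
    return out


def write_bedtimes(bedtimes: Iterable[BedtimeRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_BEDTIME_COLUMNS + ("source",))
        for b in bedtimes:
            writer.writerow(
                [
                    b.child_id,
                    "" if b.weekday_bedtime is None else format_clock_time(b.weekday_bedtime),
                    "" if b.weekend_bedtime is None else format_clock_time(b.weekend_bedtime),
                    b.source,
                ]
            )


@dataclass
class ValidationReport:
    """Tabulation of sentinel counts, coverage and invariant breaches."""

    n_records: int = 0
    n_no_time: int = 0
    n_unmatched: int = 0
    n_children: int = 0
    day_counts: dict[str, int] = field(default_factory=dict)
    n_children_with_bedtime: int = 0
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(
    records: Sequence[FoodRecord],
    bedtimes: Sequence[BedtimeRecord] = (),
) -> ValidationReport:
    """Build a validation report; never raises — problems are listed.

    Checks: sentinel tallies, duplicate (child, day, time, label) rows,
    children with more than three distinct day indices, day-type consistency
    within a day, and bedtime coverage.
    """
    report = ValidationReport(n_records=len(records))
    seen_rows: set[tuple] = set()
    days_by_child: dict[str, set[int]] = {}
    day_types: dict[tuple[str, int], set[DayType]] = {}
    for r in records:
        if r.clock_time is SentinelTime.NO_TIME:
            report.n_no_time += 1
        elif r.clock_time is SentinelTime.UNMATCHED:
            report.n_unmatched += 1
        key = (r.child_id, r.day_index, r.clock_time, r.label)
        if key in seen_rows:
            report.violations.append(
                (f"{r.child_id}/day{r.day_index}", "duplicate (child, day, time, label) row")
            )
        seen_rows.add(key)
        days_by_child.setdefault(r.child_id, set()).add(r.day_index)
        day_types.setdefault((r.child_id, r.day_index), set()).add(r.day_type)

    for child, days in days_by_child.items():
        if len(days) > 3:
            report.violations.append((child, f"more than 3 day indices: {sorted(days)}"))
    for (child, day), types in day_types.items():
        if len(types) > 1:
            report.violations.append((f"{child}/day{day}", "inconsistent day_type within day"))

    report.n_children = len(days_by_child)
    report.day_counts = {c: len(d) for c, d in sorted(days_by_child.items())}
    with_bed = {
        b.child_id
        for b in bedtimes
        if b.weekday_bedtime is not None or b.weekend_bedtime is not None
    }
    report.n_children_with_bedtime = len(with_bed & set(days_by_child))
    return report
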