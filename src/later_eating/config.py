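"""Study configuration: window boundaries, usual mealtime slots and thresholds.

All constants of the analysis live here as config defaults so that sensitivity
analyses (different windows, criteria, comparison conventions) need no code
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value violates its contract; names the field."""


@dataclass(frozen=True)
class StudyConfig:
    # daypart window start minutes: first-thing is [0, morning_start)
    morning_start: int = 360  # 06:00
    afternoon_start: int = 720  # 12:00
    evening_start: int = 1020  # 17:00

    # usual mealtime slots, inclusive minute ranges; no occasion inside a slot
    # on a day flags that meal as skipped
    breakfast_slot: tuple[int, int] = (360, 599)  # 06:00-09:59
    lunch_slot: tuple[int, int] = (720, 899)  # 12:00-14:59
    dinner_slot: tuple[int, int] = (1020, 1109)  # 17:00-18:29

    # night-eating criteria
    ne_clock_threshold: int = 1080  # 18:00; window runs to end of day
    ne_clock_criterion_pct: float = 30.0
    ne_bedtime_window: int = 120  # minutes before bedtime
    ne_bedtime_criterion_pct: float = 25.0
    ne_comparison: str = "ge"  # "ge" (default) or "gt"

    # cohort-average bedtimes used for the average-bedtime variable
    average_weekday_bedtime: int = 1203  # 20:03
    average_weekend_bedtime: int = 1242  # 20:42

    # energy of sentinel-time records: counted in TDEI ("include_in_tdei",
    # default — energy is known, only the time is not) or dropped ("exclude")
    sentinel_energy_policy: str = "include_in_tdei"

    # display choice in summaries: |skewness| above this -> median (IQR)
    skew_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.morning_start < self.afternoon_start < self.evening_start < 1440:
            raise ConfigError("daypart starts must be ordered within (0, 1440)")
        for name in ("ne_clock_threshold",):
            v = getattr(self, name)
            if not 0 <= v < 1440:
                raise ConfigError(f"{name} must lie in [0, 1439], got {v}")
        for name in ("ne_clock_criterion_pct", "ne_bedtime_criterion_pct"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ConfigError(f"{name} must lie in (0, 100), got {v}")
        if self.ne_bedtime_window <= 0:
            raise ConfigError("ne_bedtime_window must be positive")
        if self.ne_comparison not in ("ge", "gt"):
            raise ConfigError(f"ne_comparison must be 'ge' or 'gt', got {self.ne_comparison!r}")
        if self.sentinel_energy_policy not in ("include_in_tdei", "exclude"):
            raise ConfigError(
                "sentinel_energy_policy must be 'include_in_tdei' or 'exclude', "
                f"got {self.sentinel_energy_policy!r}"
            )
        for name in ("breakfast_slot", "lunch_slot", "dinner_slot"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi < 1440:
                raise ConfigError(f"{name} must be an ordered range inside [0, 1439]")
        for name in ("average_weekday_bedtime", "average_weekend_bedtime"):
            v = getattr(self, name)
            if not 0 <= v < 1440:
                raise ConfigError(f"{name} must lie in [0, 1439], got {v}")

    def average_bedtime(self, day_type) -> int:
        from .diary_io import DayType

        if day_type is DayType.WEEKDAY or day_type == "weekday":
            return self.average_weekday_bedtime
        return self.average_weekend_bedtime

    def ne_meets(self, share_pct: float, criterion_pct: float) -> bool:
        if self.ne_comparison == "ge":
            return share_pct >= criterion_pct
        return share_pct > criterion_pct

    def with_overrides(self, **kwargs) -> "StudyConfig":
        for key in kwargs:
            if key not in self.__dataclass_fields__:
                raise ConfigError(f"unknown config field {key!r}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in kwargs.items()
        }
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls().with_overrides(**data)
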