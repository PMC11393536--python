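from __future__ import annotations

import numpy as np
import pytest

from later_eating.config import StudyConfig
from later_eating.derivation import build_day_profiles
from later_eating.synthetic_data import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(GeneratorParams(n_children=40, seed=11, p_incomplete_days=0.2,
                                           p_missing_bedtime=0.1, p_no_time=0.02,
                                           p_unmatched=0.02))


@pytest.fixture(scope="session")
def large_cohort():
    """Complete, clean n=2000 cohort for recovery/identity checks."""
    return generate_cohort(
        GeneratorParams(n_children=2000, seed=7, p_incomplete_days=0.0,
                        p_missing_bedtime=0.0)
    )


@pytest.fixture(scope="session")
def large_days(large_cohort, config):
    days_by_child, beds = build_day_profiles(
        large_cohort.records, large_cohort.bedtimes, config
    )
    return days_by_child, beds


# Boundary-recoverable generator: breakfast shifted/widened so the first bin
# of the morning window carries visible mass at the default epsilon.
RECOVERY_PARAMS = GeneratorParams(
    n_children=2000,
    seed=7,
    meal_time_means=(460.0, 765.0, 1065.0),
    meal_time_sds=(40.0, 30.0, 30.0),
    uniform_mix=0.15,
    p_incomplete_days=0.0,
    p_missing_bedtime=0.0,
)


@pytest.fixture(scope="session")
def recovery_cohort():
    return generate_cohort(RECOVERY_PARAMS)


# Cohort tuned so the 75th percentile of per-child after-18:00 %TDEI lands in
# [27.5, 32.5): dinner always after 18:00, no evening snack, tight day-level
# noise, wider child-level spread.
CALIBRATION_PARAMS = GeneratorParams(
    n_children=2000,
    seed=13,
    meal_time_means=(480.0, 765.0, 1140.0),
    meal_time_sds=(30.0, 30.0, 20.0),
    meal_time_windows=((360, 599), (720, 899), (1080, 1260)),
    uniform_mix=0.0,
    snack_probabilities=(1.0, 1.0, 0.0),
    energy_shares=(0.215, 0.10, 0.28, 0.12, 0.28, 0.005),
    share_concentration_child=220.0,
    share_concentration_day=5000.0,
    p_incomplete_days=0.0,
    p_missing_bedtime=0.0,
)


@pytest.fixture(scope="session")
def calibration_cohort():
    return generate_cohort(CALIBRATION_PARAMS)


def records_to_rows(records):
    """FoodRecords -> plain tuples for the independent reference."""
    rows = []
    for r in records:
        minutes = r.clock_time if r.has_time else None
        rows.append((r.child_id, r.day_index, r.day_type.value, minutes, r.energy))
    return rows


def random_child_rows(rng: np.random.Generator, child_id: str):
    """Raw rows for one random child: arbitrary times/energies, 1-3 days.

    Stress case generator for oracle equivalence: uniform times (no trimodal
    structure), occasional sentinel rows, occasional shared times.
    """
    n_days = int(rng.integers(1, 4))
    day_types = rng.choice(["weekday", "weekend"], size=n_days)
    rows = []
    for day in range(1, n_days + 1):
        n_rec = int(rng.integers(1, 9))
        times = rng.integers(0, 1440, size=n_rec)
        if n_rec > 2 and rng.random() < 0.3:
            times[1] = times[0]  # force a shared-time occasion
        for t in times:
            minutes = int(t)
            if rng.random() < 0.05:
                minutes = None  # sentinel
            rows.append(
                (child_id, day, str(day_types[day - 1]), minutes,
                 float(np.round(rng.uniform(5, 600), 1)))
            )
    return rows


def random_bedtimes(rng: np.random.Generator):
    if rng.random() < 0.1:
        return (None, None)
    return (int(rng.integers(1100, 1350)), int(rng.integers(1100, 1350)))
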