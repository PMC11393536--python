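"""End-to-end orchestration: simulate -> validate -> derive -> calibrate ->
summarise, driven by a single YAML config, with a run manifest for
reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration, summaries
from .config import ConfigError, StudyConfig
from .derivation import Stratum, build_day_profiles, derive_all, profiles_to_frame
from .diary_io import read_bedtimes, read_diary, validate_cohort, write_bedtimes, write_diary
from .synthetic_data import GeneratorParams, generate_cohort

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_KNOWN_KEYS = {"seed", "out_dir", "simulate", "diary", "bedtimes", "study", "stages", "epsilon"}
_DEFAULT_STAGES = ("validate", "derive", "calibrate", "summarise")


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the configured stages in order; abort on the first failure.

    Config keys: ``seed``, ``out_dir``, ``simulate`` (generator parameter
    overrides; presence enables the simulate stage), ``diary``/``bedtimes``
    (input CSVs when not simulating), ``study`` (StudyConfig overrides) and
    ``stages``.
    """
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    seed = raw.get("seed")
    out_dir = Path(raw.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    study = StudyConfig().with_overrides(**(raw.get("study") or {}))
    stages = tuple(raw.get("stages") or _DEFAULT_STAGES)
    manifest = RunManifest(config=raw, seed=seed)

    def _timed(stage):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                manifest.stage_seconds[stage] = round(time.perf_counter() - self.t0, 4)
                return False

        return _Timer()

    def _emit(path: Path) -> None:
        manifest.outputs.append(str(path))

    # --- inputs: simulate or load -------------------------------------------
    if "simulate" in raw:
        with _timed("simulate"):
            overrides = dict(raw.get("simulate") or {})
            if seed is not None:
                overrides.setdefault("seed", seed)
            try:
                params = GeneratorParams(**{
                    k: tuple(map(tuple, v)) if v and isinstance(v, list) and isinstance(v[0], list)
                    else tuple(v) if isinstance(v, list) else v
                    for k, v in overrides.items()
                })
            except TypeError as exc:
                raise ConfigError(f"simulate: {exc}") from exc
            cohort = generate_cohort(params)
            diary_path = out_dir / "diary.csv"
            bed_path = out_dir / "bedtimes.csv"
            write_diary(cohort.records, diary_path)
            write_bedtimes(cohort.bedtimes, bed_path)
            cohort.truth.to_csv(out_dir / "truth.csv", index=False)
            (out_dir / "generator_params.yaml").write_text(
                yaml.safe_dump(params.to_dict(), sort_keys=True)
            )
            for p in (diary_path, bed_path, out_dir / "truth.csv", out_dir / "generator_params.yaml"):
                _emit(p)
            records, bedtimes = cohort.records, cohort.bedtimes
    else:
        for key in ("diary", "bedtimes"):
            if key not in raw:
                raise ConfigError(f"config must provide {key!r} (or a simulate section)")
            if not Path(raw[key]).exists():
                raise PipelineError("load", f"input file {raw[key]} does not exist")
        diary_path, bed_path = Path(raw["diary"]), Path(raw["bedtimes"])
        records = read_diary(diary_path)
        bedtimes = read_bedtimes(bed_path)

    manifest.input_digests = {str(diary_path): _sha256(diary_path), str(bed_path): _sha256(bed_path)}

    # --- stages --------------------------------------------------------------
    if "validate" in stages:
        with _timed("validate"):
            report = validate_cohort(records, bedtimes)
            path = out_dir / "validation.json"
            path.write_text(json.dumps(report.__dict__, indent=2, default=str))
            _emit(path)
            for ref, rule in report.violations:
                manifest.warnings.append(f"validate: {ref}: {rule}")

    days_by_child = None
    profiles_frame = None
    if {"derive", "calibrate", "summarise"} & set(stages):
        days_by_child, _beds = build_day_profiles(records, bedtimes, study)

    if "derive" in stages:
        with _timed("derive"):
            profiles, issues = derive_all(records, bedtimes, study)
            profiles_frame = profiles_to_frame(profiles)
            path = out_dir / "ler_profiles.csv"
            profiles_frame.to_csv(path, index=False)
            _emit(path)
            for child, reason in issues:
                manifest.warnings.append(f"derive: {child}: {reason}")

    if "calibrate" in stages:
        with _timed("calibrate"):
            all_days = [d for days in days_by_child.values() for d in days]
            bed_minutes = [
                bt
                for b in bedtimes
                for bt in (b.weekday_bedtime, b.weekend_bedtime)
                if bt is not None
            ]
            profile = calibration.compute_ei_profile(all_days, bed_minutes)
            report: dict = {
                "n_days": profile.n_days,
                "bin_minutes": calibration.BIN_MINUTES,
                "mean_pct_tdei": [round(v, 6) for v in profile.values.tolist()],
            }
            try:
                inference = calibration.infer_window_boundaries(
                    profile, epsilon=float(raw.get("epsilon", 0.5))
                )
                report["daypart_starts"] = list(inference.daypart_starts)
                report["meal_slots"] = [list(s) for s in inference.meal_slots]
            except calibration.CalibrationError as exc:
                manifest.warnings.append(f"calibrate: {exc}")
            candidates = {
                "after_16:00": (960, 1439),
                "after_17:00": (960 + 60, 1439),
                "after_18:00": (1080, 1439),
                "after_19:00": (1140, 1439),
                "evening_main_meal": "evening_main_meal",
                "evening_snacks": "evening_snacks",
                "pre_bedtime": "pre_bedtime",
            }
            table = calibration.compare_candidate_windows(days_by_child, candidates)
            report["candidates"] = table.to_dict(orient="records")
            try:
                decision = calibration.calibrate_ne_threshold(
                    days_by_child, (study.ne_clock_threshold, 1439)
                )
                report["ne_threshold"] = {
                    "criterion_pct": decision.criterion_pct,
                    "raw_percentile_value": decision.raw_percentile_value,
                    "prevalence_pct": decision.prevalence_pct,
                    "accepted": decision.accepted,
                }
            except calibration.CalibrationError as exc:
                manifest.warnings.append(f"calibrate: {exc}")
            path = out_dir / "calibration.json"
            path.write_text(json.dumps(report, indent=2))
            _emit(path)

    if "summarise" in stages:
        with _timed("summarise"):
            if profiles_frame is None:
                profiles, _ = derive_all(records, bedtimes, study)
                profiles_frame = profiles_to_frame(profiles)
            for stratum in Stratum:
                summ = summaries.summarise(
                    profiles_frame, stratum, skew_threshold=study.skew_threshold
                )
                path = out_dir / f"summary_{stratum.value}.txt"
                path.write_text(summaries.render_summary_table(summ) + "\n")
                _emit(path)
                corr = summaries.spearman_matrix(profiles_frame, stratum)
                path = out_dir / f"spearman_{stratum.value}.csv"
                corr.coefficients.to_csv(path)
                _emit(path)
            comp = summaries.compare_week_weekend(profiles_frame)
            comp_frame = [
                {
                    "variable": c.variable,
                    "test": c.test,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "n_pairs": c.n_pairs,
                    "mean_difference": c.mean_difference,
                    "ci95_low": c.ci95[0] if c.ci95 else None,
                    "ci95_high": c.ci95[1] if c.ci95 else None,
                }
                for c in comp
            ]
            import pandas as pd

            path = out_dir / "week_vs_weekend.csv"
            pd.DataFrame(comp_frame).to_csv(path, index=False)
            _emit(path)

            flow = summaries.flow_counts(days_by_child)
            path = out_dir / "sample_flow.json"
            path.write_text(json.dumps(flow.__dict__, indent=2))
            _emit(path)

    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    return manifest
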