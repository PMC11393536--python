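# later-eating

Analysis pipeline for **later eating rhythm (LER)** in children: from
time-stamped food-diary records and usual bedtimes to 13 derived
timing/energy/frequency variables, night-eating classification, threshold
calibration and cohort summaries — exercisable end-to-end on a built-in
synthetic cohort generator (no restricted data required).

## What it does

- **`diary_io`** — read/write long-format diary CSVs (one row per timed
  food/drink) and per-child bedtime tables; parse `HH:MM`/`HHMM` times and the
  raw sentinel codes `99` (no recorded time) / `88` (database food not matched);
  re-code exact times to the historical 7-interval coarse meal slots; cohort
  validation reports.
- **`synthetic_data`** — seeded generator of diary + bedtime cohorts with a
  trimodal eating-time density (breakfast/lunch/dinner peaks, near-zero
  troughs before 06:00/12:00/17:00), Dirichlet energy shares, weekday/weekend
  bedtime structure, sentinels and missingness; emits a per-day truth table
  for parameter-recovery tests.
- **`occasion_builder`** — eating occasions (records sharing one recorded
  time), main-meal/snack classification (largest occasion per
  morning/afternoon/evening window, earliest wins ties), meal-skipping flags
  against the usual mealtime slots.
- **`derivation`** — the 13 variables per child × stratum (whole week /
  weekdays / weekend): days eating after individual or average bedtime
  (T1a/T1b), evening main-meal and last-occasion timing (T2/T3), evening /
  pre-bedtime / main-meal / snack energy shares (E1a/E1b/E2/E3, ratio-of-sums
  %TDEI), night-eating day counts (E1c1 ≥30 %TDEI after 18:00, E1c2 ≥25 %TDEI
  within 2 h before bedtime), evening eating frequency (F1/F2/F3).
- **`calibration`** — half-hour energy-intake profile, daypart-boundary
  inference from profile troughs, candidate-window quartile comparison with
  near-duplicate flagging, and percentile-based night-eating threshold
  calibration against a reference prevalence band.
- **`summaries`** — per-variable summaries (mean/SD vs median/IQR by skewness,
  binned categoricals), paired week-vs-weekend tests (paired t / Wilcoxon
  signed-rank / chi-square), Pearson chi-square for contingency tables,
  13×13 Spearman inter-correlation matrices, sample-flow accounting.
- **`pipeline` / `cli`** — YAML-configured orchestration with a reproducible
  run manifest.

## CLI

```bash
ler simulate --n 2000 --seed 7 --out-dir data/        # synthetic cohort + truth
ler validate --diary data/diary.csv --bedtimes data/bedtimes.csv
ler derive   --diary data/diary.csv --bedtimes data/bedtimes.csv \
             --out profiles.csv                       # one row per child x stratum
ler calibrate --diary data/diary.csv --bedtimes data/bedtimes.csv --out cal.json
ler summarise --profiles profiles.csv --out-dir summaries/
ler report    --profiles profiles.csv --stratum whole_week
ler run --config run.yaml                             # full pipeline + manifest
```

Exit codes: 0 success, 2 validation failure, 3 configuration error.
Every analysis constant (window boundaries, usual meal slots, night-eating
criteria, average bedtimes, sentinel-energy policy) is a `StudyConfig` field
overridable from YAML, so sensitivity analyses need no code changes.

Example `run.yaml`:

```yaml
seed: 7
out_dir: out
simulate: {n_children: 500, p_incomplete_days: 0.1}
study: {ne_clock_criterion_pct: 30.0}
stages: [validate, derive, calibrate, summarise]
```

## Data formats

- diary CSV: `child_id, day_index, day_type, time, energy_kcal, label`
  (`time` as `HH:MM`/`HHMM`, or `99`/`88` sentinels; `day_type`
  weekday/weekend; `day_index` 1–3)
- bedtime CSV: `child_id, weekday_bedtime, weekend_bedtime` (`HH:MM`, blank =
  missing)
- profiles CSV: `child_id, stratum, n_days, T1a…F3, flags`
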