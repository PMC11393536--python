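"""Cohort description and inference: per-variable summaries, paired
week-vs-weekend comparisons, contingency statistics, rank correlations and
sample-flow accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .derivation import VARIABLE_NAMES, Stratum, bin_day_count

__all__ = [
    "VARIABLE_TYPES",
    "VariableSummary",
    "ComparisonResult",
    "CorrelationMatrix",
    "FlowReport",
    "summarise",
    "compare_week_weekend",
    "chi_square_from_table",
    "spearman_matrix",
    "flow_counts",
    "render_summary_table",
]

# continuous: mean/SD or median/IQR by skewness; count: median/IQR;
# categorical: binned day counts as n (%)
VARIABLE_TYPES: dict[str, str] = {
    "T1a": "categorical",
    "T1b": "categorical",
    "T2": "continuous",
    "T3": "continuous",
    "E1a": "continuous",
    "E1b": "continuous",
    "E1c1": "categorical",
    "E1c2": "categorical",
    "E2": "continuous",
    "E3": "continuous",
    "F1": "count",
    "F2": "categorical",
    "F3": "categorical",
}


@dataclass
class VariableSummary:
    variable: str
    stratum: Stratum
    var_type: str
    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q25: float | None = None
    q75: float | None = None
    skewness: float | None = None
    display: str = ""  # "mean_sd", "median_iqr" or "categories"
    categories: dict[str, tuple[int, float]] = field(default_factory=dict)  # label -> (n, %)


def _stratum_frame(profiles: pd.DataFrame, stratum: Stratum) -> pd.DataFrame:
    return profiles.loc[profiles["stratum"] == stratum.value]


def summarise(
    profiles: pd.DataFrame,
    stratum: Stratum,
    skew_threshold: float = 1.0,
    group_top_below_pct: float = 4.0,
) -> list[VariableSummary]:
    """Summarise every variable for one stratum.

    Continuous variables with |sample skewness| above the threshold get the
    median (IQR) display, others mean (SD); count variables always median
    (IQR); categorical variables are binned day counts reported as n (%).
    When the top category of a whole-week categorical holds less than
    ``group_top_below_pct`` percent, it is merged into the one below
    (e.g. 2 and 3 days become ">=2").
    """
    frame = _stratum_frame(profiles, stratum)
    out: list[VariableSummary] = []
    if frame.empty:
        import warnings

        warnings.warn(f"no profiles in stratum {stratum.value}", stacklevel=2)
    for var in VARIABLE_NAMES:
        var_type = VARIABLE_TYPES[var]
        values = pd.to_numeric(frame[var], errors="coerce").dropna() if not frame.empty else pd.Series(dtype=float)
        summary = VariableSummary(
            variable=var, stratum=stratum, var_type=var_type, n=int(values.size)
        )
        if var_type == "categorical":
            counts: dict[str, int] = {}
            for v in values:
                label = bin_day_count(int(v), stratum)
                counts[label] = counts.get(label, 0) + 1
            labels = sorted(counts, key=_category_sort_key)
            if values.size and labels:
                top = labels[-1]
                if (
                    len(labels) > 1
                    and 100.0 * counts[top] / values.size < group_top_below_pct
                ):
                    merged = f">={_category_sort_key(labels[-2])}"
                    counts[merged] = counts.pop(top) + counts.pop(labels[-2])
                    labels = labels[:-2] + [merged]
            summary.categories = {
                lab: (counts[lab], 100.0 * counts[lab] / values.size) for lab in labels
            }
            summary.display = "categories"
        else:
            if values.size:
                summary.mean = float(values.mean())
                summary.sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
                summary.median = float(values.median())
                summary.q25 = float(values.quantile(0.25))
                summary.q75 = float(values.quantile(0.75))
                summary.skewness = (
                    float(stats.skew(values, bias=False)) if values.size > 2 else 0.0
                )
            if var_type == "count":
                summary.display = "median_iqr"
            else:
                skewed = summary.skewness is not None and abs(summary.skewness) > skew_threshold
                summary.display = "median_iqr" if skewed else "mean_sd"
        out.append(summary)
    return out


def _category_sort_key(label: str) -> int:
    return int(label.lstrip(">="))


@dataclass
class ComparisonResult:
    variable: str
    test: str  # paired_t, wilcoxon_signed_rank or chi_square
    statistic: float | None
    p_value: float | None
    n_pairs: int
    mean_difference: float | None = None  # week minus weekend
    ci95: tuple[float, float] | None = None
    note: str = ""


def _paired_t(week: np.ndarray, weekend: np.ndarray) -> ComparisonResult:
    diff = week - weekend
    n = diff.size
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean_diff == 0.0:
            # identical pairs: no evidence of any difference
            stat, p = 0.0, 1.0
        else:
            # exactly constant nonzero shift: unbounded evidence
            stat, p = float(np.sign(mean_diff)) * np.inf, 0.0
        return ComparisonResult(
            variable="", test="paired_t", statistic=stat, p_value=p,
            n_pairs=n, mean_difference=mean_diff, ci95=(mean_diff, mean_diff),
        )
    se = sd / np.sqrt(n)
    t = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    half = stats.t.ppf(0.975, df=n - 1) * se
    return ComparisonResult(
        variable="", test="paired_t", statistic=float(t), p_value=float(p),
        n_pairs=n, mean_difference=mean_diff, ci95=(mean_diff - half, mean_diff + half),
    )


def compare_week_weekend(
    profiles: pd.DataFrame, skew_irrelevant: bool = True
) -> list[ComparisonResult]:
    """Paired week-vs-weekend comparison per variable.

    Only children with profiles in both strata enter; missing pairs are
    dropped variable-wise.  Continuous variables use the paired t-test, count
    variables the Wilcoxon matched-pairs signed-rank test, and categorical
    variables a chi-square over the two binned distributions.
    """
    week = _stratum_frame(profiles, Stratum.WEEKDAYS).set_index("child_id")
    weekend = _stratum_frame(profiles, Stratum.WEEKEND).set_index("child_id")
    common = week.index.intersection(weekend.index)
    week, weekend = week.loc[common], weekend.loc[common]

    results: list[ComparisonResult] = []
    for var in VARIABLE_NAMES:
        w = pd.to_numeric(week[var], errors="coerce")
        e = pd.to_numeric(weekend[var], errors="coerce")
        mask = w.notna() & e.notna()
        w_arr, e_arr = w[mask].to_numpy(float), e[mask].to_numpy(float)
        n = int(mask.sum())
        var_type = VARIABLE_TYPES[var]
        if n < 2:
            results.append(
                ComparisonResult(
                    variable=var, test="undefined", statistic=None, p_value=None,
                    n_pairs=n, note="fewer than 2 complete pairs",
                )
            )
            continue
        if var_type == "continuous":
            res = _paired_t(w_arr, e_arr)
            res.variable = var
        elif var_type == "count":
            diff = w_arr - e_arr
            if np.all(diff == 0):
                res = ComparisonResult(
                    variable=var, test="wilcoxon_signed_rank", statistic=0.0,
                    p_value=1.0, n_pairs=n, note="all differences zero",
                )
            else:
                stat, p = stats.wilcoxon(w_arr, e_arr, zero_method="wilcox")
                res = ComparisonResult(
                    variable=var, test="wilcoxon_signed_rank",
                    statistic=float(stat), p_value=float(p), n_pairs=n,
                )
        else:  # categorical: strata bin differently, so compare 0 vs >=1 day
            table = np.array(
                [
                    [int((w_arr == 0).sum()), int((w_arr >= 1).sum())],
                    [int((e_arr == 0).sum()), int((e_arr >= 1).sum())],
                ]
            )
            table = table[:, table.sum(axis=0) > 0]
            if table.shape[1] < 2:
                res = ComparisonResult(
                    variable=var, test="chi_square", statistic=0.0, p_value=1.0,
                    n_pairs=n, note="single category",
                )
            else:
                stat, df_, p = chi_square_from_table(table)
                res = ComparisonResult(
                    variable=var, test="chi_square", statistic=stat, p_value=p, n_pairs=n
                )
        results.append(res)
    return results


def chi_square_from_table(counts) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for an r x c table.

    Returns (statistic, degrees of freedom, p-value); zero marginals are an
    error.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("counts must be a non-negative 2-D table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column marginal")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class CorrelationMatrix:
    coefficients: pd.DataFrame  # 13 x 13 Spearman rho
    n: pd.DataFrame  # pairwise non-missing counts
    undefined: list[tuple[str, str]] = field(default_factory=list)


def spearman_matrix(profiles: pd.DataFrame, stratum: Stratum) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations between the 13 variables.

    Constant variables give NaN cells recorded in ``undefined`` rather than a
    silent zero; average ranks are used for ties.
    """
    frame = _stratum_frame(profiles, stratum)
    data = frame[list(VARIABLE_NAMES)].apply(pd.to_numeric, errors="coerce")
    k = len(VARIABLE_NAMES)
    rho = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    undefined: list[tuple[str, str]] = []
    for i, vi in enumerate(VARIABLE_NAMES):
        for j in range(i, k):
            vj = VARIABLE_NAMES[j]
            pair = data[[vi, vj]].dropna()
            n_mat[i, j] = n_mat[j, i] = len(pair)
            if i == j:
                rho[i, i] = 1.0 if len(pair) else np.nan
                continue
            if len(pair) < 3:
                undefined.append((vi, vj))
                continue
            x, y = pair[vi].to_numpy(), pair[vj].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                undefined.append((vi, vj))
                continue
            r = stats.spearmanr(x, y).statistic
            rho[i, j] = rho[j, i] = float(r)
    idx = list(VARIABLE_NAMES)
    return CorrelationMatrix(
        coefficients=pd.DataFrame(rho, index=idx, columns=idx),
        n=pd.DataFrame(n_mat, index=idx, columns=idx),
        undefined=undefined,
    )


@dataclass
class FlowReport:
    """Sample-flow accounting from invitation to analysis strata."""

    invited: int | None = None
    completed: int | None = None
    timed: int | None = None
    n_incomplete: int | None = None  # fewer than three recorded days
    n_all_weekday: int | None = None  # three weekdays, no weekend day
    whole_week: int | None = None
    weekdays: int | None = None
    weekend: int | None = None
    week_and_weekend: int | None = None

    @property
    def response_rate_pct(self) -> float | None:
        if self.invited and self.completed is not None:
            return 100.0 * self.completed / self.invited
        return None


def flow_counts(
    days_by_child: Mapping[str, Sequence] | None = None,
    *,
    invited: int | None = None,
    completed: int | None = None,
    timed: int | None = None,
    n_incomplete: int | None = None,
    n_all_weekday: int | None = None,
) -> FlowReport:
    """Stage counts of the sample flow.

    With a cohort (child -> day profiles) the stage counts are derived from
    the data; printed upstream counts (invited, completed) can be supplied as
    keywords.  Without a cohort the report is pure arithmetic on the supplied
    counts: whole_week = timed - n_incomplete, week_and_weekend =
    whole_week - n_all_weekday.
    """
    report = FlowReport(invited=invited, completed=completed)
    if days_by_child is not None:
        from .derivation import Stratum, stratify_days

        report.timed = len(days_by_child)
        report.n_incomplete = sum(1 for d in days_by_child.values() if len(d) < 3)
        report.whole_week = report.timed - report.n_incomplete
        n_wd = n_we = n_both = n_all_wd = 0
        for days in days_by_child.values():
            strata = stratify_days(days)
            whole = Stratum.WHOLE_WEEK in strata
            if Stratum.WEEKDAYS in strata:
                n_wd += 1
            if Stratum.WEEKEND in strata:
                n_we += 1
            if whole and Stratum.WEEKEND in strata:
                n_both += 1
            if whole and Stratum.WEEKEND not in strata:
                n_all_wd += 1
        report.weekdays = n_wd
        report.weekend = n_we
        report.n_all_weekday = n_all_wd
        report.week_and_weekend = n_both
        return report

    report.timed = timed
    report.n_incomplete = n_incomplete
    report.n_all_weekday = n_all_weekday
    if timed is not None and n_incomplete is not None:
        report.whole_week = timed - n_incomplete
    if report.whole_week is not None and n_all_weekday is not None:
        report.week_and_weekend = report.whole_week - n_all_weekday
    return report


def render_summary_table(summaries: Iterable[VariableSummary]) -> str:
    """Plain-text rendering of a stratum's variable summaries."""
    lines = []
    for s in summaries:
        if s.display == "categories":
            cats = "; ".join(
                f"{lab}: {n} ({pct:.1f}%)" for lab, (n, pct) in s.categories.items()
            )
            lines.append(f"{s.variable:<5} n={s.n:<6} {cats}")
        elif s.display == "median_iqr" and s.median is not None:
            lines.append(
                f"{s.variable:<5} n={s.n:<6} median {s.median:.2f} "
                f"(IQR {s.q25:.2f}, {s.q75:.2f})"
            )
        elif s.mean is not None:
            lines.append(f"{s.variable:<5} n={s.n:<6} mean {s.mean:.2f} (SD {s.sd:.2f})")
        else:
            lines.append(f"{s.variable:<5} n={s.n:<6} (no data)")
    return "\n".join(lines)
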