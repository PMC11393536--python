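"""Straight-loop reference implementation of the 13 variables.

Deliberately independent of the package: operates on plain tuples
``(child_id, day_index, day_type, time_minutes_or_None, energy)`` plus a
bedtime mapping, and follows the printed definitions one day and one
occasion at a time.  Used as the oracle for equivalence tests.
"""

from __future__ import annotations

import statistics

EVENING_START = 1020
DINNER_SLOT = (1020, 1109)
NE_CLOCK = 1080
AVG_BED = {"weekday": 1203, "weekend": 1242}


def _occasions(day_rows):
    """time -> kcal for timed rows, sorted times."""
    by_time = {}
    for (_c, _d, _t, minutes, kcal) in day_rows:
        if minutes is not None:
            by_time[minutes] = by_time.get(minutes, 0.0) + kcal
    return dict(sorted(by_time.items()))


def _evening_main(occ):
    evening = {t: e for t, e in occ.items() if t >= EVENING_START}
    if not evening:
        return None
    best_t, best_e = None, -1.0
    for t in sorted(evening):
        if evening[t] > best_e:  # strictly greater: earliest wins ties
            best_t, best_e = t, evening[t]
    return best_t


def reference_profile(rows, bedtimes, stratum):
    """Derive one child's variables for one stratum from raw rows.

    rows: list of (child_id, day_index, day_type, minutes_or_None, kcal)
    bedtimes: (weekday_bedtime_or_None, weekend_bedtime_or_None)
    stratum: "whole_week" | "weekdays" | "weekend"
    Returns a dict of the 13 variables (None = missing/not eligible).
    """
    days = {}
    for row in rows:
        days.setdefault(row[1], []).append(row)
    day_list = [(idx, days[idx][0][2], days[idx]) for idx in sorted(days)]

    if stratum == "whole_week":
        if len(day_list) != 3:
            return None
        member = day_list
    elif stratum == "weekdays":
        member = [d for d in day_list if d[1] == "weekday"]
        if len(member) < 2:
            return None
    else:
        member = [d for d in day_list if d[1] == "weekend"]
        if len(member) < 1:
            return None

    wd_bed, we_bed = bedtimes
    out = {}

    # ---- timing ------------------------------------------------------------
    t1a, t1b = 0, 0
    t1a_ok = True
    main_times, last_times = [], []
    for _idx, day_type, day_rows in member:
        occ = _occasions(day_rows)
        bed = wd_bed if day_type == "weekday" else we_bed
        if bed is None:
            t1a_ok = False
        elif any(t > bed for t in occ):
            t1a += 1
        if any(t > AVG_BED[day_type] for t in occ):
            t1b += 1
        main = _evening_main(occ)
        if main is not None:
            main_times.append(main)
        if occ:
            last_times.append(max(occ))
    out["T1a"] = t1a if t1a_ok else None
    out["T1b"] = t1b
    out["T2"] = sum(main_times) / len(main_times) if main_times else None
    out["T3"] = sum(last_times) / len(last_times) if last_times else None

    # ---- energy (ratio of sums) -------------------------------------------
    tdei_by_day = {}
    for idx, _dt, day_rows in member:
        tdei_by_day[idx] = sum(r[4] for r in day_rows)  # sentinel energy included
    if any(v <= 0 for v in tdei_by_day.values()):
        out.update({k: None for k in ("E1a", "E1b", "E2", "E3", "E1c1", "E1c2")})
    else:
        tdei_sum = sum(tdei_by_day.values())
        evening_sum = e2_sum = e3_sum = prebed_sum = 0.0
        e1b_ok = True
        e1c1 = 0
        e1c2, e1c2_ok = 0, True
        for idx, day_type, day_rows in member:
            occ = _occasions(day_rows)
            main = _evening_main(occ)
            for t, e in occ.items():
                if t >= EVENING_START:
                    evening_sum += e
                    if main is not None and t == main:
                        e2_sum += e
                    else:
                        e3_sum += e
            bed = wd_bed if day_type == "weekday" else we_bed
            if bed is None:
                e1b_ok = False
                e1c2_ok = False
            else:
                prebed = sum(e for t, e in occ.items() if bed - 120 <= t <= bed)
                prebed_sum += prebed
                if 100.0 * prebed / tdei_by_day[idx] >= 25.0:
                    e1c2 += 1
            after_1800 = sum(e for t, e in occ.items() if t >= NE_CLOCK)
            if 100.0 * after_1800 / tdei_by_day[idx] >= 30.0:
                e1c1 += 1
        out["E1a"] = 100.0 * evening_sum / tdei_sum
        out["E2"] = 100.0 * e2_sum / tdei_sum
        out["E3"] = 100.0 * e3_sum / tdei_sum
        out["E1b"] = 100.0 * prebed_sum / tdei_sum if e1b_ok else None
        out["E1c1"] = e1c1
        out["E1c2"] = e1c2 if e1c2_ok else None

    # ---- frequency ---------------------------------------------------------
    counts, f2, f3 = [], 0, 0
    for _idx, _dt, day_rows in member:
        occ = _occasions(day_rows)
        counts.append(sum(1 for t in occ if t >= EVENING_START))
        if any(DINNER_SLOT[0] <= t <= DINNER_SLOT[1] for t in occ):
            f2 += 1
        main = _evening_main(occ)
        if main is not None and any(t > main for t in occ if t >= EVENING_START):
            f3 += 1
    out["F1"] = statistics.median(counts)
    out["F2"] = f2
    out["F3"] = f3
    return out
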