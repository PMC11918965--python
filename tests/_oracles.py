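"""Independent oracles for the test suite.

The brute-force person-trial enumerator literally walks each participant's
timeline with plain Python loops, independent of the vectorized builder,
and re-derives treatment, time zero, era, outcome linkage and the
time-zero severity snapshot from first principles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _midx(ts: pd.Timestamp) -> int:
    return ts.year * 12 + ts.month - 1


def _parse_dose_raw(raw):
    """(dose_month_idx, exact_date_for_era) mirroring the documented rule:
    month-only values resolve to the 15th for era comparison."""
    if raw is None or raw == "" or (isinstance(raw, float) and np.isnan(raw)):
        return None, None
    s = str(raw).strip()
    if len(s) == 7:  # YYYY-MM
        month = pd.Timestamp(s + "-01")
        return _midx(month), month + pd.Timedelta(days=14)
    d = pd.Timestamp(s)
    return _midx(d), d


def enumerate_person_trials(
    assessments: pd.DataFrame,
    trial_months: list[str],
    era_cutoff: str,
    window: tuple[int, int] = (2, 5),
) -> pd.DataFrame:
    """Brute-force construction of the person-trial table."""
    cutoff = pd.Timestamp(era_cutoff)
    t_midx = [_midx(pd.Timestamp(m)) for m in trial_months]
    lo, hi = window

    rows = []
    for pid, grp in assessments.groupby("participant_id"):
        recs = {}
        for _, r in grp.iterrows():
            m = _midx(pd.Timestamp(r["assessment_month"]))
            recs[m] = r
        months_sorted = sorted(recs)

        def outcome_at(tz: int):
            for m in months_sorted:
                if tz + lo <= m <= tz + hi:
                    r = recs[m]
                    return r.get("gad7_total"), r.get("phq8_total"), m
            return pd.NA, pd.NA, None

        def severity_at(tz: int, col: str):
            val = pd.NA
            for m in months_sorted:
                if m > tz:
                    break
                v = recs[m].get(col)
                if v is not None and not pd.isna(v):
                    val = v
            return val

        done = False
        for k, tm in enumerate(t_midx, start=1):
            if done or tm not in recs:
                continue
            r = recs[tm]
            status = r.get("vaccinated_ever")
            if status is None or pd.isna(status):
                continue  # status not reported: skip this trial only
            if int(status) == 0:
                tz = tm
                era = "universal" if (
                    pd.Timestamp(year=tz // 12, month=tz % 12 + 1, day=15) >= cutoff
                ) else "preuniversal"
                g, p, om = outcome_at(tz)
                rows.append(
                    dict(participant_id=pid, trial_index=k, treatment=0,
                         time_zero_idx=tz, era=era, outcome_gad7=g,
                         outcome_phq8=p, outcome_midx=om,
                         anxiety_t0=severity_at(tz, "gad7_mod_severe"),
                         depression_t0=severity_at(tz, "phq8_mod_severe"))
                )
            else:
                done = True  # first vaccinated report at a trial: last entry
                dose_midx, dose_exact = _parse_dose_raw(r.get("first_dose_date"))
                if dose_midx is None:
                    continue  # missing dose date: vaccinated entry skipped
                tz = dose_midx
                era = "universal" if dose_exact >= cutoff else "preuniversal"
                g, p, om = outcome_at(tz)
                rows.append(
                    dict(participant_id=pid, trial_index=k, treatment=1,
                         time_zero_idx=tz, era=era, outcome_gad7=g,
                         outcome_phq8=p, outcome_midx=om,
                         anxiety_t0=severity_at(tz, "gad7_mod_severe"),
                         depression_t0=severity_at(tz, "phq8_mod_severe"))
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
        for col in ("outcome_gad7", "outcome_phq8", "anxiety_t0", "depression_t0"):
            out[col] = out[col].astype("Int64")
    return out


def random_toy_cohort(rng: np.random.Generator, n_max: int = 20) -> pd.DataFrame:
    """A small random cohort exercising skipped waves, mid-quarter and
    month-only dose dates, missing statuses and missing scores."""
    months = pd.to_datetime(
        ["2020-12-01", "2021-03-01", "2021-06-01", "2021-09-01", "2021-12-01", "2022-03-01"]
    )
    all_midx = [_midx(m) for m in months]
    n = int(rng.integers(1, n_max + 1))
    rows = []
    for pid in range(1, n + 1):
        present = [m for m in months if rng.random() < 0.8]
        if not present:
            present = [months[int(rng.integers(len(months)))]]
        first_m = _midx(min(present))
        dose_midx = None
        dose_str = ""
        if rng.random() < 0.55:
            # any calendar month Dec 2020..Dec 2021, at/after the first assessment
            lo_m = max(first_m, _midx(pd.Timestamp("2020-12-01")))
            hi_m = _midx(pd.Timestamp("2021-12-01"))
            if lo_m <= hi_m:
                dose_midx = int(rng.integers(lo_m, hi_m + 1))
                y, mo = divmod(dose_midx, 12)
                if rng.random() < 0.3:
                    dose_str = f"{y:04d}-{mo + 1:02d}"  # month-only report
                else:
                    day = int(rng.integers(1, 29))
                    dose_str = f"{y:04d}-{mo + 1:02d}-{day:02d}"
                if rng.random() < 0.1:
                    dose_str = ""  # vaccinated but dose date never reported
        for m in present:
            mi = _midx(m)
            vacc = int(dose_midx is not None and dose_midx <= mi)
            status = vacc if rng.random() > 0.1 else pd.NA
            g = int(rng.integers(0, 22)) if rng.random() > 0.15 else pd.NA
            p = int(rng.integers(0, 25)) if rng.random() > 0.15 else pd.NA
            rows.append(
                dict(
                    participant_id=pid,
                    assessment_month=m.strftime("%Y-%m-%d"),
                    vaccinated_ever=status,
                    first_dose_date=dose_str if (vacc and not pd.isna(status)) else "",
                    gad7_total=g,
                    phq8_total=p,
                    gad7_mod_severe=(pd.NA if pd.isna(g) else int(g >= 10)),
                    phq8_mod_severe=(pd.NA if pd.isna(p) else int(p >= 10)),
                    education=str(rng.choice(["a", "b", "c"])),
                )
            )
    df = pd.DataFrame(rows)
    df["gad7_total"] = df["gad7_total"].astype("Int64")
    df["phq8_total"] = df["phq8_total"].astype("Int64")
    df["gad7_mod_severe"] = df["gad7_mod_severe"].astype("Int64")
    df["phq8_mod_severe"] = df["phq8_mod_severe"].astype("Int64")
    df["vaccinated_ever"] = df["vaccinated_ever"].astype("Int64")
    return df


def expand_2x2(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Person-trial-shaped rows for a 2x2 table, one cluster per row."""
    treatment = [1] * (a + b) + [0] * (c + d)
    outcome = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame(
        {
            "participant_id": np.arange(len(treatment)),
            "treatment": treatment,
            "outcome": outcome,
        }
    )
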