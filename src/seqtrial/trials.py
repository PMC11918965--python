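"""Sequential trial emulation: eligibility, treatment assignment, time zero,
era classification, person-trial expansion and outcome linkage.

The observational analysis is conceptualized as a sequence of nonrandomized
trials run at successive assessment waves.  At each trial wave, participants
who completed that assessment and reported vaccination status enter:
still-unvaccinated participants contribute an unvaccinated person-trial
(time zero = assessment month) and may re-enter later trials until
vaccinated; newly vaccinated participants contribute exactly one vaccinated
person-trial at the first trial where the vaccination is reported (time
zero = month of first dose) and never re-enter.  The outcome is the symptom
score at the first completed assessment 2-5 months after time zero
(typically ~3 months).  Era (preuniversal vs. universal vaccine
availability) is assigned from the exact first-dose date for vaccinated
person-trials and from the time-zero month for unvaccinated ones; month
values are resolved to the month's mid-point (day 15) when an exact date is
unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

PRE = "preuniversal"
UNI = "universal"

DEFAULT_TRIAL_MONTHS = ("2020-12", "2021-03", "2021-06", "2021-09", "2021-12")
DEFAULT_ERA_CUTOFF = "2021-04-19"

#: columns updated at every wave rather than fixed at enrollment
TIME_UPDATED_COLS = ("employment", "food_insecurity", "housing_instability")
OUTCOME_COLS = ("gad7_total", "phq8_total", "gad7_mod_severe", "phq8_mod_severe")
STRUCTURAL_COLS = (
    "participant_id", "assessment_month", "vaccinated_ever", "first_dose_date",
) + OUTCOME_COLS + TIME_UPDATED_COLS


@dataclass
class TrialConfig:
    trial_months: Sequence[str] = DEFAULT_TRIAL_MONTHS
    era_cutoff: str = DEFAULT_ERA_CUTOFF
    outcome_lag_window: tuple[int, int] = (2, 5)

    def __post_init__(self):
        months = [pd.Timestamp(m) for m in self.trial_months]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError("trial_months must be strictly increasing")
        lo, hi = self.outcome_lag_window
        if lo > hi:
            raise ValidationError("outcome_lag_window is empty")

    @property
    def months(self) -> list[pd.Timestamp]:
        return [pd.Timestamp(m).normalize().replace(day=1) for m in self.trial_months]


def month_index(ts: pd.Series | pd.Timestamp) -> pd.Series | int:
    """Months since year 0 — calendar-month arithmetic."""
    if isinstance(ts, pd.Timestamp):
        return ts.year * 12 + (ts.month - 1)
    return ts.dt.year * 12 + (ts.dt.month - 1)


def month_midpoint(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.normalize().replace(day=1) + pd.Timedelta(days=14)


def assign_era(date: pd.Timestamp, cutoff: pd.Timestamp | str) -> str:
    """Universal era iff the date is on or after the cutoff (2021-04-19)."""
    if date is None or pd.isna(date):
        raise ValidationError("cannot assign era: date is missing")
    return UNI if pd.Timestamp(date) >= pd.Timestamp(cutoff) else PRE


def _parse_dose(raw) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Return (month-of-dose, exact-date-for-era).  A month-only value
    ('YYYY-MM') is resolved to the mid-month (day 15) for era comparison."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return pd.NaT, pd.NaT
    if isinstance(raw, str) and len(raw.strip()) == 7:  # YYYY-MM
        month = pd.Timestamp(raw.strip() + "-01")
        return month, month_midpoint(month)
    d = pd.Timestamp(raw)
    return d.normalize().replace(day=1), d


def normalize_assessments(assessments: pd.DataFrame) -> pd.DataFrame:
    """Parse dates, derive month indices, and validate structural contracts."""
    df = assessments.copy()
    df["assessment_month"] = (
        pd.to_datetime(df["assessment_month"]).dt.normalize().apply(lambda t: t.replace(day=1))
    )
    df["month_idx"] = month_index(df["assessment_month"])

    dup = df.duplicated(subset=["participant_id", "month_idx"])
    if dup.any():
        pid = df.loc[dup, "participant_id"].iloc[0]
        raise DataError(f"participant {pid}: more than one record in a month")

    df["vaccinated_ever"] = pd.to_numeric(df["vaccinated_ever"], errors="coerce").astype("Int64")
    if "first_dose_date" not in df.columns:
        df["first_dose_date"] = ""
    parsed = df["first_dose_date"].apply(_parse_dose)
    df["dose_month"] = [p[0] for p in parsed]
    df["dose_date_exact"] = [p[1] for p in parsed]

    has_dose = df["dose_month"].notna()
    vacc = (df["vaccinated_ever"] == 1).fillna(False).astype(bool)
    not_vacc = (df["vaccinated_ever"] == 0).fillna(False).astype(bool)
    if (has_dose & not_vacc).any():
        pid = df.loc[has_dose & not_vacc, "participant_id"].iloc[0]
        raise DataError(f"participant {pid}: first_dose_date present but not vaccinated")

    dose_midx = month_index(pd.to_datetime(df["dose_month"]))
    bad_order = (vacc & has_dose & (dose_midx > df["month_idx"])).fillna(False).astype(bool)
    if bad_order.any():
        pid = df.loc[bad_order, "participant_id"].iloc[0]
        raise DataError(f"participant {pid}: first dose date after its reporting assessment")

    df = df.sort_values(["participant_id", "month_idx"], kind="mergesort").reset_index(drop=True)
    # vaccination must be absorbing among reported statuses
    status = df.dropna(subset=["vaccinated_ever"])
    decreasing = (
        status.groupby("participant_id")["vaccinated_ever"].diff().lt(0).fillna(False).astype(bool)
    )
    if decreasing.any():
        bad = status.loc[decreasing, "participant_id"].unique().tolist()
        raise DataError(f"non-monotone vaccination history for participants {bad}")
    return df


def build_person_trials(assessments: pd.DataFrame, cfg: TrialConfig | None = None) -> pd.DataFrame:
    """Expand a long assessment table into one row per person-trial."""
    cfg = cfg or TrialConfig()
    df = normalize_assessments(assessments)
    cutoff = pd.Timestamp(cfg.era_cutoff)
    trial_idx_by_month = {month_index(m): i + 1 for i, m in enumerate(cfg.months)}

    trial_rows = df[df["month_idx"].isin(trial_idx_by_month) & df["vaccinated_ever"].notna()].copy()
    trial_rows["trial_index"] = trial_rows["month_idx"].map(trial_idx_by_month)

    vacc_rows = trial_rows[trial_rows["vaccinated_ever"] == 1]
    first_vacc_midx = vacc_rows.groupby("participant_id")["month_idx"].min()

    # --- unvaccinated entries: one per eligible trial until vaccination ---
    unvacc = trial_rows[trial_rows["vaccinated_ever"] == 0].copy()
    unvacc["treatment"] = 0
    unvacc["time_zero"] = unvacc["assessment_month"]
    unvacc["tz_idx"] = unvacc["month_idx"]
    unvacc["era"] = [
        assign_era(month_midpoint(m), cutoff) for m in unvacc["time_zero"]
    ]

    # --- vaccinated entries: first trial where vaccination is reported ---
    entry = vacc_rows.merge(
        first_vacc_midx.rename("first_midx"), left_on="participant_id", right_index=True
    )
    entry = entry[entry["month_idx"] == entry["first_midx"]].copy()
    no_dose = entry["dose_month"].isna()
    if no_dose.any():
        skipped = entry.loc[no_dose, "participant_id"].tolist()
        logger.warning(
            "excluding %d vaccinated entr%s with missing first-dose date: %s",
            len(skipped), "y" if len(skipped) == 1 else "ies", skipped,
        )
        entry = entry[~no_dose]
    entry["treatment"] = 1
    entry["time_zero"] = pd.to_datetime(entry["dose_month"])
    entry["tz_idx"] = month_index(entry["time_zero"])
    entry["era"] = [assign_era(d, cutoff) for d in entry["dose_date_exact"]]

    cols = ["participant_id", "trial_index", "treatment", "time_zero", "tz_idx", "era",
            "first_dose_date"]
    pt = pd.concat([unvacc[cols], entry[cols]], ignore_index=True)
    pt = pt.sort_values(["participant_id", "trial_index"], kind="mergesort").reset_index(drop=True)

    pt = link_outcome(pt, df, cfg)
    pt = snapshot_covariates(pt, df)
    pt["time_zero"] = pt["time_zero"].dt.strftime("%Y-%m-%d")
    pt["outcome_month"] = pt["outcome_month"].dt.strftime("%Y-%m-%d")
    return pt.drop(columns=["tz_idx"])


def link_outcome(person_trials: pd.DataFrame, assessments: pd.DataFrame,
                 cfg: TrialConfig) -> pd.DataFrame:
    """Attach the score at the first completed assessment whose lag from time
    zero falls inside the outcome window (earliest match wins); missing if no
    such assessment or the score is missing."""
    lo, hi = cfg.outcome_lag_window
    right = assessments[["participant_id", "month_idx", "assessment_month",
                         "gad7_total", "phq8_total"]].copy()
    right = right.rename(columns={
        "assessment_month": "outcome_month",
        "gad7_total": "outcome_gad7", "phq8_total": "outcome_phq8",
        "month_idx": "outcome_midx",
    }).sort_values("outcome_midx", kind="mergesort")

    left = person_trials.copy()
    left["search_idx"] = left["tz_idx"] + lo
    left = left.sort_values("search_idx", kind="mergesort")
    merged = pd.merge_asof(
        left, right,
        left_on="search_idx", right_on="outcome_midx",
        by="participant_id", direction="forward",
    )
    too_late = (merged["outcome_midx"].notna()
                & (merged["outcome_midx"] > merged["tz_idx"] + hi)).to_numpy(dtype=bool)
    merged.loc[too_late, "outcome_month"] = pd.NaT
    merged.loc[too_late, ["outcome_gad7", "outcome_phq8"]] = pd.NA
    merged.loc[too_late, "outcome_midx"] = np.nan
    merged["outcome_month"] = pd.to_datetime(merged["outcome_month"])
    merged["outcome_gad7"] = merged["outcome_gad7"].astype("Int64")
    merged["outcome_phq8"] = merged["outcome_phq8"].astype("Int64")
    return (
        merged.drop(columns=["search_idx", "outcome_midx"])
        .sort_values(["participant_id", "trial_index"], kind="mergesort")
        .reset_index(drop=True)
    )


def snapshot_covariates(person_trials: pd.DataFrame, assessments: pd.DataFrame) -> pd.DataFrame:
    """Attach baseline covariates (from enrollment) and time-updated
    covariates plus symptom severity as of the most recent measure at or
    before time zero."""
    pt = person_trials.copy()

    baseline_cols = [
        c for c in assessments.columns
        if c not in STRUCTURAL_COLS and c not in ("month_idx", "dose_month", "dose_date_exact")
    ]
    enrol = (
        assessments.sort_values("month_idx", kind="mergesort")
        .groupby("participant_id", as_index=False)
        .first()[["participant_id"] + baseline_cols]
    )
    pt = pt.merge(enrol, on="participant_id", how="left")

    # any person-trial must have at least one assessment at/before time zero
    first_midx = assessments.groupby("participant_id")["month_idx"].min()
    fm = pt["participant_id"].map(first_midx)
    orphan = fm.isna() | (fm > pt["tz_idx"])
    if orphan.any():
        pid = pt.loc[orphan, "participant_id"].iloc[0]
        raise DataError(f"participant {pid}: no assessment at or before time zero")

    def _asof(col_in: str, col_out: str, require_value: bool) -> None:
        right = assessments[["participant_id", "month_idx", col_in]]
        if require_value:
            right = right[right[col_in].notna()]
        right = right.rename(columns={"month_idx": "_midx", col_in: col_out})
        right = right.sort_values("_midx", kind="mergesort")
        nonlocal pt
        left = pt.sort_values("tz_idx", kind="mergesort")
        pt = (
            pd.merge_asof(
                left, right, left_on="tz_idx", right_on="_midx",
                by="participant_id", direction="backward",
            )
            .drop(columns=["_midx"])
            .sort_values(["participant_id", "trial_index"], kind="mergesort")
            .reset_index(drop=True)
        )

    for col in TIME_UPDATED_COLS:
        if col in assessments.columns:
            _asof(col, col, require_value=True)
    snap_map = {
        "gad7_mod_severe": "anxiety_t0",
        "phq8_mod_severe": "depression_t0",
        "gad7_total": "gad7_t0",
        "phq8_total": "phq8_t0",
    }
    for col_in, col_out in snap_map.items():
        if col_in in assessments.columns:
            _asof(col_in, col_out, require_value=True)
    for col in ("anxiety_t0", "depression_t0"):
        if col in pt.columns:
            pt[col] = pt[col].astype("Int64")
    return pt


@dataclass
class FlowSummary:
    """Counts mirroring a study-flow diagram."""

    n_enrolled: int
    n_eligible: int
    n_person_trials: int
    n_vaccinated_person_trials: int
    n_vaccinated_pre: int
    n_vaccinated_uni: int

    @property
    def vaccinated_share_pre(self) -> float:
        nv = self.n_vaccinated_person_trials
        return 100.0 * self.n_vaccinated_pre / nv if nv else float("nan")

    @property
    def vaccinated_share_uni(self) -> float:
        nv = self.n_vaccinated_person_trials
        return 100.0 * self.n_vaccinated_uni / nv if nv else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_eligible": self.n_eligible,
            "n_person_trials": self.n_person_trials,
            "n_vaccinated_person_trials": self.n_vaccinated_person_trials,
            "n_vaccinated_pre": self.n_vaccinated_pre,
            "n_vaccinated_uni": self.n_vaccinated_uni,
            "vaccinated_share_pre": self.vaccinated_share_pre,
            "vaccinated_share_uni": self.vaccinated_share_uni,
        }


def flow_accounting(assessments: pd.DataFrame, person_trials: pd.DataFrame) -> FlowSummary:
    vacc = person_trials[person_trials["treatment"] == 1]
    return FlowSummary(
        n_enrolled=int(assessments["participant_id"].nunique()),
        n_eligible=int(person_trials["participant_id"].nunique()),
        n_person_trials=int(len(person_trials)),
        n_vaccinated_person_trials=int(len(vacc)),
        n_vaccinated_pre=int((vacc["era"] == PRE).sum()),
        n_vaccinated_uni=int((vacc["era"] == UNI).sum()),
    )
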