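import numpy as np
import pandas as pd
import pytest

from seqtrial import DataError, TrialConfig, ValidationError, assign_era, build_person_trials
from seqtrial.trials import PRE, UNI, flow_accounting, month_midpoint

from _oracles import enumerate_person_trials, random_toy_cohort
from conftest import toy_assessments

TRIAL_MONTHS = ["2020-12-01", "2021-03-01", "2021-06-01", "2021-09-01", "2021-12-01"]


@pytest.mark.parametrize(
    "date, era",
    [
        ("2021-04-18", PRE),
        ("2021-04-19", UNI),   # cutoff day itself is universal
        ("2020-12-15", PRE),
        ("2022-01-01", UNI),
    ],
)
def test_assign_era_boundary(date, era):
    assert assign_era(pd.Timestamp(date), "2021-04-19") == era


def test_assign_era_missing_date_raises():
    with pytest.raises(ValidationError):
        assign_era(pd.NaT, "2021-04-19")


def _wave_rows(pid, statuses, dose=""):
    """statuses: list of (month, vaccinated_ever) tuples."""
    return [
        dict(participant_id=pid, assessment_month=m, vaccinated_ever=s,
             first_dose_date=(dose if s == 1 else ""))
        for m, s in statuses
    ]


def test_never_vaccinated_reenters_every_trial():
    df = toy_assessments(_wave_rows(1, [(m, 0) for m in TRIAL_MONTHS]))
    pt = build_person_trials(df)
    assert len(pt) == 5
    assert pt["treatment"].eq(0).all()
    assert pt["trial_index"].tolist() == [1, 2, 3, 4, 5]
    assert pt["time_zero"].tolist() == TRIAL_MONTHS


def test_vaccination_midway_gives_two_unvaccinated_then_one_vaccinated():
    df = toy_assessments(
        _wave_rows(
            1,
            [("2020-12-01", 0), ("2021-03-01", 0), ("2021-06-01", 1),
             ("2021-09-01", 1), ("2021-12-01", 1)],
            dose="2021-05-20",
        )
    )
    pt = build_person_trials(df)
    assert len(pt) == 3
    assert pt["treatment"].tolist() == [0, 0, 1]
    assert pt["trial_index"].tolist() == [1, 2, 3]
    vacc = pt.iloc[2]
    assert vacc["time_zero"] == "2021-05-01"  # month of first dose
    assert vacc["era"] == UNI  # 2021-05-20 >= cutoff


def test_already_vaccinated_at_entry_contributes_one_trial():
    df = toy_assessments(
        _wave_rows(1, [(m, 1) for m in TRIAL_MONTHS], dose="2020-12-14")
    )
    pt = build_person_trials(df)
    assert len(pt) == 1
    assert pt.iloc[0]["treatment"] == 1
    assert pt.iloc[0]["trial_index"] == 1
    assert pt.iloc[0]["era"] == PRE


def test_outcome_window_rules():
    rows = _wave_rows(1, [("2020-12-01", 0)])
    rows.append(dict(participant_id=1, assessment_month="2021-03-01",
                     vaccinated_ever=0, gad7_total=12, phq8_total=3))
    rows.append(dict(participant_id=1, assessment_month="2021-04-01",
                     vaccinated_ever=0, gad7_total=20, phq8_total=20))
    df = toy_assessments(rows)
    pt = build_person_trials(df)
    t1 = pt[pt["trial_index"] == 1].iloc[0]
    # lag-3 assessment (Mar) is the first in the 2..5 window: earliest wins
    assert t1["outcome_gad7"] == 12
    assert t1["outcome_month"] == "2021-03-01"


def test_outcome_missing_when_no_assessment_in_window():
    df = toy_assessments(
        _wave_rows(1, [("2020-12-01", 0), ("2021-09-01", 0)])  # lag 9: too late
    )
    pt = build_person_trials(df)
    t1 = pt[pt["trial_index"] == 1].iloc[0]
    assert pd.isna(t1["outcome_gad7"]) and pd.isna(t1["outcome_month"])


def test_severity_snapshot_falls_back_to_earlier_wave():
    rows = [
        dict(participant_id=1, assessment_month="2020-12-01", vaccinated_ever=0,
             gad7_total=15, gad7_mod_severe=1),
        dict(participant_id=1, assessment_month="2021-03-01", vaccinated_ever=0,
             gad7_total=pd.NA, gad7_mod_severe=pd.NA),  # missing at time zero
        dict(participant_id=1, assessment_month="2021-06-01", vaccinated_ever=0,
             gad7_total=3, gad7_mod_severe=0),
    ]
    pt = build_person_trials(toy_assessments(rows))
    by_trial = pt.set_index("trial_index")
    assert by_trial.loc[1, "anxiety_t0"] == 1   # measured at time zero itself
    assert by_trial.loc[2, "anxiety_t0"] == 1   # falls back to December value
    assert by_trial.loc[3, "anxiety_t0"] == 0


def test_status_missing_skips_trial_but_allows_reentry():
    rows = _wave_rows(1, [("2020-12-01", 0)])
    rows.append(dict(participant_id=1, assessment_month="2021-03-01",
                     vaccinated_ever=pd.NA))
    rows += _wave_rows(1, [("2021-06-01", 0)])
    pt = build_person_trials(toy_assessments(rows))
    assert pt["trial_index"].tolist() == [1, 3]


def test_month_only_dose_resolves_to_midpoint_for_era():
    # April 2021 month-only dose: April 15 < April 19 -> preuniversal
    rows = _wave_rows(1, [("2020-12-01", 0), ("2021-03-01", 0)])
    rows.append(dict(participant_id=1, assessment_month="2021-06-01",
                     vaccinated_ever=1, first_dose_date="2021-04"))
    pt = build_person_trials(toy_assessments(rows))
    vacc = pt[pt["treatment"] == 1].iloc[0]
    assert vacc["era"] == PRE
    assert vacc["time_zero"] == "2021-04-01"


def test_data_errors_name_the_participant():
    non_monotone = toy_assessments(
        _wave_rows(1, [("2020-12-01", 1), ("2021-03-01", 0)], dose="2020-12-10")
    )
    with pytest.raises(DataError, match="non-monotone"):
        build_person_trials(non_monotone)

    dose_after_report = toy_assessments(
        _wave_rows(1, [("2020-12-01", 1)], dose="2021-02-01")
    )
    with pytest.raises(DataError, match="after its reporting assessment"):
        build_person_trials(dose_after_report)

    dup = toy_assessments(_wave_rows(1, [("2020-12-01", 0), ("2020-12-15", 0)]))
    with pytest.raises(DataError, match="more than one record"):
        build_person_trials(dup)

    orphan = toy_assessments(
        [dict(participant_id=7, assessment_month="2021-06-01", vaccinated_ever=1,
              first_dose_date="2021-01-10")]
    )
    with pytest.raises(DataError, match="no assessment at or before time zero"):
        build_person_trials(orphan)


def test_missing_dose_date_drops_vaccinated_entry_only():
    rows = _wave_rows(1, [("2020-12-01", 0), ("2021-03-01", 0)])
    rows.append(dict(participant_id=1, assessment_month="2021-06-01",
                     vaccinated_ever=1, first_dose_date=""))
    pt = build_person_trials(toy_assessments(rows))
    assert pt["treatment"].tolist() == [0, 0]


def test_invariants_on_random_cohorts():
    rng = np.random.default_rng(99)
    for _ in range(10):
        df = random_toy_cohort(rng)
        pt = build_person_trials(df)
        if pt.empty:
            continue
        per = pt.groupby("participant_id")
        assert (per["treatment"].sum() <= 1).all()       # one vaccinated entry max
        assert (per.size() <= 5).all()                   # at most K person-trials
        assert pt["era"].isin([PRE, UNI]).all()          # era partition
        # no trial after the first vaccinated entry
        for _, g in per:
            if (g["treatment"] == 1).any():
                k = g.loc[g["treatment"] == 1, "trial_index"].iloc[0]
                assert g["trial_index"].max() == k


def test_builder_matches_bruteforce_on_one_cohort():
    rng = np.random.default_rng(1234)
    df = random_toy_cohort(rng)
    got = build_person_trials(df)
    exp = enumerate_person_trials(df, TRIAL_MONTHS, "2021-04-19")
    cols = ["participant_id", "trial_index", "treatment", "era",
            "outcome_gad7", "outcome_phq8", "anxiety_t0", "depression_t0"]
    assert len(got) == len(exp)
    if len(exp):
        got_c = got[cols].reset_index(drop=True)
        exp_c = exp[cols].reset_index(drop=True).astype(got_c.dtypes.to_dict())
        pd.testing.assert_frame_equal(got_c, exp_c, check_dtype=False)


def test_flow_accounting_partitions(small_cohort):
    pt = build_person_trials(small_cohort.assessments)
    flow = flow_accounting(small_cohort.assessments, pt)
    assert flow.n_vaccinated_pre + flow.n_vaccinated_uni == flow.n_vaccinated_person_trials
    assert flow.vaccinated_share_pre + flow.vaccinated_share_uni == pytest.approx(100.0)
    assert flow.n_person_trials == len(pt)
    assert flow.n_eligible <= flow.n_enrolled
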