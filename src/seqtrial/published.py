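"""Published person-trial counts from the motivating cohort analysis.

These printed counts — person-trial denominators and numbers with
moderate-to-severe symptoms by era and vaccination status, from a U.S.
national online cohort analysis of COVID-19 vaccination and anxiety /
depression symptoms (assessments December 2020 through March 2022) — serve
as inputs for validating the descriptive estimators (prevalence intervals,
2x2 odds ratios, era shares) against the percentages the source tables
print.  Only count-derived descriptives can be reproduced from printed
tables; the published adjusted effect estimates require the underlying
individual-level cohort.
"""

from __future__ import annotations

from .estimation import ContingencyTable

#: overall flow: person-trials and vaccinated person-trials by era
FLOW = {
    "n_participants_enrolled": 6740,
    "n_participants_eligible": 4832,
    "n_person_trials": 11482,
    "n_vaccinated_person_trials": 3987,
    "n_vaccinated_pre": 3191,
}

#: era -> outcome -> vaccination status -> (n with moderate/severe symptoms,
#: person-trial denominator); full-cohort table
COHORT_COUNTS = {
    "preuniversal": {
        "anxiety": {"not_vaccinated": (1171, 4846), "vaccinated": (532, 3194)},
        "depression": {"not_vaccinated": (1231, 4846), "vaccinated": (653, 3194)},
    },
    "universal": {
        "anxiety": {"not_vaccinated": (706, 2628), "vaccinated": (219, 801)},
        "depression": {"not_vaccinated": (782, 2628), "vaccinated": (234, 801)},
    },
}

#: same layout for the subgroups with moderate/severe symptoms at time zero
SUBGROUP_COUNTS = {
    "preuniversal": {
        "anxiety": {"not_vaccinated": (840, 1292), "vaccinated": (361, 656)},
        "depression": {"not_vaccinated": (895, 1325), "vaccinated": (461, 730)},
    },
    "universal": {
        "anxiety": {"not_vaccinated": (494, 739), "vaccinated": (142, 208)},
        "depression": {"not_vaccinated": (549, 789), "vaccinated": (153, 222)},
    },
}

#: printed prevalence percentages corresponding to COHORT_COUNTS/SUBGROUP_COUNTS
PRINTED_PREVALENCE = {
    ("cohort", "preuniversal", "anxiety", "not_vaccinated"): 24.2,
    ("cohort", "preuniversal", "anxiety", "vaccinated"): 16.7,
    ("cohort", "preuniversal", "depression", "not_vaccinated"): 25.4,
    ("cohort", "preuniversal", "depression", "vaccinated"): 20.4,
    ("cohort", "universal", "anxiety", "not_vaccinated"): 26.9,
    ("cohort", "universal", "anxiety", "vaccinated"): 27.3,
    ("cohort", "universal", "depression", "not_vaccinated"): 29.8,
    ("cohort", "universal", "depression", "vaccinated"): 29.2,
    ("subgroup", "preuniversal", "anxiety", "not_vaccinated"): 65.0,
    ("subgroup", "preuniversal", "anxiety", "vaccinated"): 55.0,
    ("subgroup", "preuniversal", "depression", "not_vaccinated"): 67.5,
    ("subgroup", "preuniversal", "depression", "vaccinated"): 63.2,
    ("subgroup", "universal", "anxiety", "not_vaccinated"): 66.8,
    ("subgroup", "universal", "anxiety", "vaccinated"): 68.3,
    ("subgroup", "universal", "depression", "not_vaccinated"): 69.6,
    ("subgroup", "universal", "depression", "vaccinated"): 68.9,
}

#: printed preuniversal share of vaccinated person-trials, percent
PRINTED_PRE_SHARE = 80.0


def contingency(era: str, outcome: str, table: str = "cohort") -> ContingencyTable:
    """2x2 table (a,b treated with/without outcome; c,d untreated) from the
    printed counts."""
    src = COHORT_COUNTS if table == "cohort" else SUBGROUP_COUNTS
    sev_v, den_v = src[era][outcome]["vaccinated"]
    sev_u, den_u = src[era][outcome]["not_vaccinated"]
    return ContingencyTable(a=sev_v, b=den_v - sev_v, c=sev_u, d=den_u - sev_u)
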