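"""Publication-style tables from the person-trial table and analysis report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trials import PRE, UNI

#: baseline covariates tabulated in the characteristics table, in print order
TABLE1_CATEGORICAL = (
    "age_band", "gender", "race_ethnicity", "income", "education",
    "employment", "children_in_household", "housing_instability",
    "food_insecurity", "exposure_risk", "susceptibility",
    "healthcare_access_barriers",
)
TABLE1_SCORES = (("gad7_t0", "anxiety_t0"), ("phq8_t0", "depression_t0"))


def _fmt_ci(vals) -> str:
    p, lo, hi = vals
    return f"{p:.1f} ({lo:.1f}, {hi:.1f})"


def _fmt_est(d: dict | None) -> str:
    if not d:
        return ""
    lo, hi = d["or_ci95"] if "or" in d else d["ci95"]
    point = d.get("or", d["point"])
    return f"{point:.2f} ({lo:.2f}, {hi:.2f})"


def make_table1(person_trials: pd.DataFrame) -> pd.DataFrame:
    """Counts and column percentages by era x vaccination status, plus
    mean/SD and median/IQR of the symptom scores at time zero."""
    blocks = {"overall": person_trials}
    for era in (PRE, UNI):
        for trt, label in ((0, "not_vaccinated"), (1, "vaccinated")):
            blocks[f"{era}_{label}"] = person_trials[
                (person_trials["era"] == era) & (person_trials["treatment"] == trt)
            ]

    rows = []
    rows.append(
        {"variable": "person_trials", "level": "N",
         **{k: str(len(v)) for k, v in blocks.items()}}
    )
    for var in TABLE1_CATEGORICAL:
        if var not in person_trials.columns:
            continue
        levels = sorted(person_trials[var].dropna().astype(str).unique())
        for lev in levels:
            row = {"variable": var, "level": lev}
            for k, v in blocks.items():
                n = int((v[var].astype(str) == lev).sum())
                pct = 100.0 * n / len(v) if len(v) else float("nan")
                row[k] = f"{n} ({pct:.1f})"
            rows.append(row)
    for score_col, sev_col in TABLE1_SCORES:
        if score_col not in person_trials.columns:
            continue
        mrow = {"variable": score_col, "level": "mean (SD)"}
        qrow = {"variable": score_col, "level": "median (IQR)"}
        srow = {"variable": sev_col, "level": "moderate/severe n (%)"}
        for k, v in blocks.items():
            x = pd.to_numeric(v[score_col], errors="coerce").dropna()
            if len(x):
                mrow[k] = f"{x.mean():.2f} ({x.std():.2f})"
                qrow[k] = f"{x.median():.0f} ({x.quantile(0.25):.0f}, {x.quantile(0.75):.0f})"
            else:
                mrow[k] = qrow[k] = ""
            sev = pd.to_numeric(v.get(sev_col), errors="coerce").dropna() if sev_col in v else pd.Series(dtype=float)
            if len(sev):
                n = int((sev == 1).sum())
                srow[k] = f"{n} ({100.0 * n / len(sev):.1f})"
            else:
                srow[k] = ""
        rows.extend([mrow, qrow, srow])
    return pd.DataFrame(rows)


def make_effects_table(report: dict, subgroup: bool = False) -> pd.DataFrame:
    """Era x vaccination-status rows with person-trial denominator, N,
    prevalence (95% CI), crude OR and adjusted (pooled) OR; for the
    subgroup table also the mixed-model score coefficient."""
    rows = []
    for outcome, entry in report["outcomes"].items():
        for era, e in entry["eras"].items():
            desc = e.get("subgroup_descriptive" if subgroup else "descriptive")
            adj = e.get("subgroup" if subgroup else "adjusted")
            if desc is None:
                continue
            for label in ("not_vaccinated", "vaccinated"):
                d = desc.get(label, {})
                row = {
                    "outcome": outcome,
                    "era": era,
                    "status": label,
                    "person_trial_denominator": d.get("person_trials", 0),
                    "n_severe": d.get("n_severe", 0),
                    "prevalence_95ci": _fmt_ci(d["prevalence"]) if "prevalence" in d else "",
                    "or_95ci": "1.00" if label == "not_vaccinated" else (
                        f"{desc['crude_or']:.2f} ({desc['crude_or_ci95'][0]:.2f}, {desc['crude_or_ci95'][1]:.2f})"
                        if desc.get("crude_or") else ""
                    ),
                    "aor_95ci": "1.00" if label == "not_vaccinated" else _fmt_est(adj),
                }
                if subgroup:
                    lmm = e.get("subgroup_lmm")
                    row["adj_coeff_95ci"] = (
                        "" if label == "not_vaccinated" or not lmm
                        else f"{lmm['point']:.2f} ({lmm['ci95'][0]:.2f}, {lmm['ci95'][1]:.2f})"
                    )
                rows.append(row)
    return pd.DataFrame(rows)
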