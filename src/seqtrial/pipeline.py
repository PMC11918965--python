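"""End-to-end orchestration: person-trial build -> multiple imputation ->
era-stratified fits (overall and subgroups, binary and continuous) ->
Rubin pooling -> heterogeneity tests.  Deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimation as est_mod
from .errors import EstimationError
from .estimation import (
    ContingencyTable,
    EffectEstimate,
    ModelSpec,
    crude_or,
    fit_pooled_logistic,
    fit_random_intercept_lmm,
    prevalence,
    wald_heterogeneity,
)
from .imputation import (
    DEFAULT_PREDICTORS_ANXIETY,
    DEFAULT_PREDICTORS_DEPRESSION,
    ImputationSpec,
    impute,
    rubin_pool,
)
from .instruments import Instrument
from .trials import PRE, UNI, TrialConfig, build_person_trials, flow_accounting

OUTCOMES = {
    "anxiety": {
        "total_col": "outcome_gad7",
        "instrument": Instrument.GAD7,
        "t0_col": "anxiety_t0",
        "model_outcome": "anxiety_mod_severe",
        "adjustment": est_mod.DEFAULT_ADJUSTMENT_ANXIETY,
        "predictors": DEFAULT_PREDICTORS_ANXIETY,
        "seed_offset": 11,
    },
    "depression": {
        "total_col": "outcome_phq8",
        "instrument": Instrument.PHQ8,
        "t0_col": "depression_t0",
        "model_outcome": "depression_mod_severe",
        "adjustment": est_mod.DEFAULT_ADJUSTMENT_DEPRESSION,
        "predictors": DEFAULT_PREDICTORS_DEPRESSION,
        "seed_offset": 23,
    },
}


@dataclass
class AnalysisConfig:
    """Everything run_full_analysis needs beyond the assessment table."""

    trial: TrialConfig = field(default_factory=TrialConfig)
    m: int = 20
    seed: int = 0
    threshold: int = 10
    outcomes: Sequence[str] = ("anxiety", "depression")
    adjustment: dict | None = None      # outcome -> covariate list
    mi_predictors: dict | None = None   # outcome -> predictor list
    include_design_in_imputation: bool = True
    correction: str = "CR0"
    run_subgroups: bool = True
    run_lmm: bool = True

    def adjustment_for(self, outcome: str) -> list[str]:
        if self.adjustment and outcome in self.adjustment:
            return list(self.adjustment[outcome])
        return list(OUTCOMES[outcome]["adjustment"])

    def predictors_for(self, outcome: str) -> list[str]:
        if self.mi_predictors and outcome in self.mi_predictors:
            return list(self.mi_predictors[outcome])
        return list(OUTCOMES[outcome]["predictors"])


def _est_dict(e: EffectEstimate) -> dict:
    d = {
        "scale": e.scale, "point": e.point, "se_model": e.se_model,
        "se_robust": e.se_robust, "ci95": list(e.ci95),
        "n_person_trials": e.n_person_trials, "n_participants": e.n_participants,
        "era": e.era,
    }
    if e.scale == "log_odds":
        d["or"] = e.odds_ratio
        d["or_ci95"] = list(e.or_ci95)
    return d


def _pooled_dict(p, scale: str) -> dict:
    d = {
        "scale": scale, "point": p.point, "se": p.se, "ci95": list(p.ci95),
        "within_var": p.within_var, "between_var": p.between_var,
        "total_var": p.total_var, "df": p.df, "m": p.m,
    }
    if scale == "log_odds":
        d["or"] = float(np.exp(p.point))
        d["or_ci95"] = [float(np.exp(p.ci95[0])), float(np.exp(p.ci95[1]))]
    return d


def _pool_fits(fits: list[tuple[float, float]], dfcom: float, scale: str) -> dict:
    points = [p for p, _ in fits]
    variances = [v for _, v in fits]
    return _pooled_dict(rubin_pool(points, variances, dfcom=dfcom), scale)


def _descriptives(observed: pd.DataFrame, total_col: str, threshold: int) -> dict:
    """Complete-case 2x2 descriptives within one era stratum."""
    out = {}
    tab_cells = {}
    for label, flag in (("vaccinated", 1), ("not_vaccinated", 0)):
        grp = observed[observed["treatment"] == flag]
        denom = int(len(grp))
        n_sev = int((pd.to_numeric(grp[total_col]) >= threshold).sum())
        entry = {"person_trials": denom, "n_severe": n_sev}
        if denom > 0:
            p, lo, hi = prevalence(n_sev, denom)
            entry["prevalence"] = [p, lo, hi]
        out[label] = entry
        tab_cells[label] = (n_sev, denom - n_sev)
    a, b = tab_cells["vaccinated"]
    c, d = tab_cells["not_vaccinated"]
    try:
        ce = crude_or(ContingencyTable(a, b, c, d))
        out["crude_or"] = ce.odds_ratio
        out["crude_or_ci95"] = list(ce.or_ci95)
        out["crude_log_or"] = ce.point
    except EstimationError:
        out["crude_or"] = None
    return out


def run_full_analysis(assessments: pd.DataFrame, cfg: AnalysisConfig | None = None) -> dict:
    """Run the whole emulated-trial analysis and return a JSON-serializable
    report (flow accounting, per-era pooled effects, descriptives, subgroup
    and mixed-model estimates, and the era-heterogeneity Wald test)."""
    cfg = cfg or AnalysisConfig()
    person_trials = build_person_trials(assessments, cfg.trial)
    flow = flow_accounting(assessments, person_trials)

    report: dict = {
        "seed": cfg.seed,
        "m": cfg.m,
        "flow": flow.to_dict(),
        "outcomes": {},
    }

    for outcome in cfg.outcomes:
        meta = OUTCOMES[outcome]
        total_col = meta["total_col"]
        adjustment = cfg.adjustment_for(outcome)
        predictors = cfg.predictors_for(outcome)

        required = sorted(set(adjustment) | set(predictors))
        analytic = person_trials.dropna(subset=[c for c in required if c in person_trials.columns])
        n_dropped = len(person_trials) - len(analytic)

        mi_predictors = list(predictors)
        if cfg.include_design_in_imputation:
            for extra in ("treatment", "era"):
                if extra not in mi_predictors:
                    mi_predictors.append(extra)
        spec_mi = ImputationSpec(
            outcome_col=total_col,
            instrument=meta["instrument"],
            predictors=mi_predictors,
            m=cfg.m,
            seed=cfg.seed + meta["seed_offset"],
        )
        completed = impute(analytic, spec_mi)

        entry: dict = {
            "n_analytic_person_trials": int(len(analytic)),
            "n_dropped_incomplete_covariates": int(n_dropped),
            "n_missing_outcome": int(pd.to_numeric(analytic[total_col], errors="coerce").isna().sum()),
            "eras": {},
        }

        pooled_by_era: dict[str, EffectEstimate] = {}
        for era in (PRE, UNI):
            spec = ModelSpec(
                outcome=meta["model_outcome"], adjustment=adjustment, era=era,
                threshold=cfg.threshold,
            )
            fits, dfcom = [], None
            for d in completed:
                e, f = fit_pooled_logistic(d, spec, correction=cfg.correction)
                fits.append((e.point, e.se_robust**2))
                dfcom = f.dfcom
            pooled = _pool_fits(fits, dfcom, "log_odds")

            obs = analytic[
                (analytic["era"] == era)
                & pd.to_numeric(analytic[total_col], errors="coerce").notna()
            ]
            era_entry = {
                "adjusted": pooled,
                "descriptive": _descriptives(obs, total_col, cfg.threshold),
            }
            pooled_by_era[era] = EffectEstimate(
                scale="log_odds", point=pooled["point"], se_model=pooled["se"],
                se_robust=pooled["se"], ci95=tuple(pooled["ci95"]),
                n_person_trials=int((analytic["era"] == era).sum()),
                n_participants=int(analytic.loc[analytic["era"] == era, "participant_id"].nunique()),
                era=era,
            )

            if cfg.run_subgroups:
                t0_col = meta["t0_col"]
                sub_adj = [c for c in adjustment if c != t0_col]
                sub_fits, sub_dfcom = [], None
                lmm_fits = []
                ok = True
                for d in completed:
                    sub = d[pd.to_numeric(d[t0_col], errors="coerce") == 1]
                    if sub.empty or sub["treatment"].nunique() < 2:
                        ok = False
                        break
                    sspec = ModelSpec(
                        outcome=meta["model_outcome"], adjustment=sub_adj, era=era,
                        threshold=cfg.threshold,
                    )
                    try:
                        e, f = fit_pooled_logistic(sub, sspec, correction=cfg.correction)
                    except EstimationError:
                        ok = False
                        break
                    sub_fits.append((e.point, e.se_robust**2))
                    sub_dfcom = f.dfcom
                    if cfg.run_lmm:
                        lspec = ModelSpec(
                            outcome=total_col, adjustment=sub_adj, era=era,
                        )
                        le = fit_random_intercept_lmm(sub, lspec)
                        lmm_fits.append((le.point, le.se_model**2))
                if ok:
                    era_entry["subgroup"] = _pool_fits(sub_fits, sub_dfcom, "log_odds")
                    if cfg.run_lmm:
                        era_entry["subgroup_lmm"] = _pool_fits(lmm_fits, sub_dfcom, "score_points")
                    sub0 = analytic[
                        (analytic["era"] == era)
                        & (pd.to_numeric(analytic[t0_col], errors="coerce") == 1)
                        & pd.to_numeric(analytic[total_col], errors="coerce").notna()
                    ]
                    era_entry["subgroup_descriptive"] = _descriptives(sub0, total_col, cfg.threshold)
                else:
                    era_entry["subgroup"] = None

            entry["eras"][era] = era_entry

        W, p = wald_heterogeneity(pooled_by_era[PRE], pooled_by_era[UNI])
        entry["wald_heterogeneity"] = {"statistic": W, "p_value": p}
        report["outcomes"][outcome] = entry

    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
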