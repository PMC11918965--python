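"""Synthetic longitudinal cohorts with the structure the analysis assumes.

The generator emulates a U.S. national online cohort assessed roughly
quarterly from December 2020 through March 2022, with covariate-dependent
COVID-19 vaccine uptake, a universal-eligibility era cutoff (2021-04-19),
GAD-7/PHQ-8 outcomes whose log-odds of exceeding the moderate-to-severe
threshold depend on treatment, vaccine era and confounders, and ~7% missing
outcome scores under MCAR or MAR-on-covariates.

Generative model
----------------
Baseline covariates are drawn independently per participant.  At each
assessment wave before the final outcome wave, still-unvaccinated
participants receive a first dose with probability
``expit(base_logodds[wave] + x'uptake_coefs)``; vaccination is absorbing and
the dose is reported at the wave it occurs (first-dose day defaults to the
15th of the month).  Symptom outcomes at a wave follow

    logit P(total >= 10) = alpha + theta_era * treated + x'outcome_coefs + u

where ``treated`` is 1 iff the first dose fell in a *strictly earlier*
month (the symptom response manifests by the following assessment),
``theta_era`` is the era-specific log odds ratio keyed to the first-dose
date vs. the cutoff, ``alpha`` is calibrated so the marginal prevalence
among untreated participant-waves equals ``baseline_prevalence``, and ``u``
is an optional person-level normal effect (default off).  Integer totals are
then sampled uniformly within the severe (>=10) or non-severe (<10) range,
so the continuous scale respects the threshold the estimand lives on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigError
from .instruments import Instrument, SEVERITY_THRESHOLD

DEFAULT_ASSESSMENT_MONTHS = (
    "2020-12", "2021-03", "2021-06", "2021-09", "2021-12", "2022-03",
)
DEFAULT_ERA_CUTOFF = "2021-04-19"

#: per-wave base log-odds of a first dose, calibrated a priori so that with
#: the default covariate effects roughly 80% of vaccinated person-trials
#: fall in the preuniversal era, matching the cohort structure emulated.
DEFAULT_UPTAKE_BASE = {
    "2020-12": -2.1,
    "2021-03": -0.45,
    "2021-06": -2.0,
    "2021-09": -2.85,
    "2021-12": -3.15,
}


@dataclass(frozen=True)
class Covariate:
    """A generative covariate: level labels, marginal probabilities and
    per-level log-odds effects on the outcome and on vaccine uptake
    (first level is the reference)."""

    name: str
    levels: tuple
    probs: tuple[float, ...]
    outcome_coefs: tuple[float, ...] = ()
    uptake_coefs: tuple[float, ...] = ()

    def __post_init__(self):
        k = len(self.levels)
        if len(self.probs) != k or abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError(f"covariate {self.name}: probs must sum to 1 over levels")
        for attr in ("outcome_coefs", "uptake_coefs"):
            v = getattr(self, attr)
            if v and len(v) != k:
                raise ConfigError(f"covariate {self.name}: {attr} length mismatch")

    def coefs(self, which: str) -> np.ndarray:
        v = getattr(self, which)
        return np.asarray(v if v else [0.0] * len(self.levels), dtype=float)


def default_confounders() -> tuple[Covariate, ...]:
    """One binary confounder (susceptibility to severe COVID-19) and one
    3-level education covariate, both affecting uptake and outcome."""
    return (
        Covariate(
            name="susceptibility",
            levels=(0, 1),
            probs=(0.79, 0.21),
            outcome_coefs=(0.0, 0.8),
            uptake_coefs=(0.0, 0.5),
        ),
        Covariate(
            name="education",
            levels=("hs_or_less", "some_college", "college_grad"),
            probs=(0.14, 0.28, 0.58),
            outcome_coefs=(0.3, 0.15, 0.0),
            uptake_coefs=(-0.4, -0.2, 0.0),
        ),
    )


#: purely descriptive covariates carried through the pipeline (no generative
#: effect by default): marginals loosely modeled on a diverse U.S. online
#: cohort.  Time-updated ones evolve as a slow Markov chain across waves.
DESCRIPTIVE_BASELINE = {
    "age_band": (("18-49", "50-59", "60+"), (0.71, 0.13, 0.16)),
    "gender": (("cis_male", "cis_female", "nonbinary_trans"), (0.43, 0.55, 0.02)),
    "race_ethnicity": (
        ("white_nh", "hispanic", "black_nh", "asian_pi", "other"),
        (0.60, 0.18, 0.12, 0.07, 0.03),
    ),
    "income": (("lt_50k", "50_100k", "gte_100k"), (0.42, 0.31, 0.27)),
    "children_in_household": ((0, 1), (0.68, 0.32)),
    "exposure_risk": ((0, 1), (0.62, 0.38)),
    "healthcare_access_barriers": ((0, 1), (0.57, 0.43)),
}
DESCRIPTIVE_TIME_UPDATED = {
    "employment": (("employed", "out_of_work", "other"), (0.65, 0.12, 0.23)),
    "food_insecurity": ((0, 1), (0.73, 0.27)),
    "housing_instability": ((0, 1), (0.52, 0.48)),
}
TIME_UPDATED_FLIP_PROB = 0.10  # per-wave probability of redrawing the value


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic cohort."""

    n_participants: int = 2000
    assessment_months: Sequence[str] = DEFAULT_ASSESSMENT_MONTHS
    era_cutoff: str = DEFAULT_ERA_CUTOFF
    uptake_base_logodds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UPTAKE_BASE)
    )
    true_effect_pre: float = float(np.log(0.79))
    true_effect_uni: float = float(np.log(1.23))
    baseline_prevalence: float = 0.25
    confounders: Sequence[Covariate] = field(default_factory=default_confounders)
    missing_rate: float = 0.07
    missing_mechanism: str = "MAR"  # or "MCAR"
    missing_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"food_insecurity": 0.8}
    )
    retention: float = 1.0  # per-wave probability of completing the next wave
    person_sd: float = 0.0  # latent person-level outcome effect (log-odds SD)
    dose_day: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ConfigError("baseline_prevalence must be in (0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ConfigError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        months = [pd.Timestamp(m) for m in self.assessment_months]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ConfigError("assessment_months must be strictly increasing")
        for m in self.uptake_base_logodds:
            if pd.Timestamp(m) not in months:
                raise ConfigError(f"uptake month {m} is not an assessment month")
        if not (0.0 < self.retention <= 1.0):
            raise ConfigError("retention must be in (0, 1]")

    @property
    def months(self) -> list[pd.Timestamp]:
        return [pd.Timestamp(m) for m in self.assessment_months]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["assessment_months"] = list(self.assessment_months)
        d["uptake_base_logodds"] = dict(self.uptake_base_logodds)
        d["missing_coefs"] = dict(self.missing_coefs)
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort: long assessment table plus the generating truth."""

    assessments: pd.DataFrame
    truth: dict

    def write(self, directory: str | Path, fmt: str = "csv") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            self.assessments.to_csv(directory / "assessments.csv", index=False)
        elif fmt == "parquet":
            self.assessments.to_parquet(directory / "assessments.parquet", index=False)
        else:
            raise ConfigError(f"unknown format {fmt!r}")
        (directory / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _calibrate_alpha(cfg: SyntheticConfig) -> float:
    """Intercept such that marginal P(severe | untreated) = baseline_prevalence,
    integrating over the exact joint confounder distribution (independent
    covariates) and, if person_sd > 0, over the latent person effect by
    Gauss-Hermite quadrature."""
    grids = [(cov.probs, cov.coefs("outcome_coefs")) for cov in cfg.confounders]
    combos = list(product(*[range(len(p)) for p, _ in grids])) or [()]
    pr = np.array([np.prod([grids[j][0][i] for j, i in enumerate(c)]) for c in combos])
    lp = np.array([sum(grids[j][1][i] for j, i in enumerate(c)) for c in combos])

    if cfg.person_sd > 0:
        nodes, weights = np.polynomial.hermite_e.hermegauss(31)
        weights = weights / weights.sum()
        u = nodes * cfg.person_sd
    else:
        u, weights = np.array([0.0]), np.array([1.0])

    def marginal(alpha: float) -> float:
        p = expit(alpha + lp[:, None] + u[None, :])
        return float((pr[:, None] * weights[None, :] * p).sum())

    target = cfg.baseline_prevalence
    lo, hi = -30.0, 30.0
    if not (marginal(lo) < target < marginal(hi)):
        raise ConfigError("baseline_prevalence unattainable under confounder_spec")
    return float(brentq(lambda a: marginal(a) - target, lo, hi, xtol=1e-12))


def _sample_totals(rng: np.random.Generator, severe: np.ndarray, inst: Instrument) -> np.ndarray:
    """Integer totals uniform within the class implied by the severe flag."""
    lo = np.where(severe, SEVERITY_THRESHOLD, 0)
    hi = np.where(severe, inst.max_total + 1, SEVERITY_THRESHOLD)
    return rng.integers(lo, hi)


def simulate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate one cohort; byte-identical for a fixed config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    months = cfg.months
    cutoff = pd.Timestamp(cfg.era_cutoff)
    alpha = _calibrate_alpha(cfg)

    # --- baseline covariates ---
    cols: dict[str, np.ndarray] = {}
    uptake_lp = np.zeros(n)
    outcome_lp = np.zeros(n)
    for cov in cfg.confounders:
        idx = rng.choice(len(cov.levels), size=n, p=cov.probs)
        cols[cov.name] = np.asarray(cov.levels, dtype=object)[idx]
        uptake_lp += cov.coefs("uptake_coefs")[idx]
        outcome_lp += cov.coefs("outcome_coefs")[idx]
    for name, (levels, probs) in DESCRIPTIVE_BASELINE.items():
        idx = rng.choice(len(levels), size=n, p=probs)
        cols[name] = np.asarray(levels, dtype=object)[idx]

    person_u = rng.normal(0.0, cfg.person_sd, size=n) if cfg.person_sd > 0 else np.zeros(n)

    # --- vaccination uptake (absorbing; doses occur at assessment waves) ---
    dose_wave = np.full(n, -1)  # wave index of first dose, -1 = never
    for w, month in enumerate(months):
        key = month.strftime("%Y-%m")
        if key not in {pd.Timestamp(k).strftime("%Y-%m") for k in cfg.uptake_base_logodds}:
            continue
        base = {pd.Timestamp(k).strftime("%Y-%m"): v for k, v in cfg.uptake_base_logodds.items()}[key]
        at_risk = dose_wave < 0
        p = expit(base + uptake_lp[at_risk])
        takes = rng.random(at_risk.sum()) < p
        ids = np.flatnonzero(at_risk)[takes]
        dose_wave[ids] = w

    dose_month = np.array(
        [months[w] if w >= 0 else pd.NaT for w in dose_wave], dtype=object
    )
    dose_date = np.array(
        [m + pd.Timedelta(days=cfg.dose_day - 1) if m is not pd.NaT else pd.NaT
         for m in dose_month],
        dtype=object,
    )
    dose_pre_era = np.array(
        [bool(d is not pd.NaT and d < cutoff) for d in dose_date]
    )

    # --- retention (monotone dropout) ---
    n_waves = len(months)
    if cfg.retention < 1.0:
        cont = rng.random((n, n_waves - 1)) < cfg.retention
        completed = np.ones((n, n_waves), dtype=bool)
        completed[:, 1:] = np.cumprod(cont, axis=1).astype(bool)
    else:
        completed = np.ones((n, n_waves), dtype=bool)

    # --- time-updated covariates (slow Markov chain) ---
    tu_values: dict[str, np.ndarray] = {}
    for name, (levels, probs) in DESCRIPTIVE_TIME_UPDATED.items():
        vals = np.empty((n, n_waves), dtype=object)
        idx = rng.choice(len(levels), size=n, p=probs)
        vals[:, 0] = np.asarray(levels, dtype=object)[idx]
        for w in range(1, n_waves):
            flip = rng.random(n) < TIME_UPDATED_FLIP_PROB
            idx_new = rng.choice(len(levels), size=n, p=probs)
            idx = np.where(flip, idx_new, idx)
            vals[:, w] = np.asarray(levels, dtype=object)[idx]
        tu_values[name] = vals

    # --- outcomes per wave ---
    theta = np.where(dose_pre_era, cfg.true_effect_pre, cfg.true_effect_uni)
    severe = {}
    totals = {}
    for inst in (Instrument.GAD7, Instrument.PHQ8):
        sev = np.empty((n, n_waves), dtype=bool)
        tot = np.empty((n, n_waves), dtype=np.int64)
        for w in range(n_waves):
            treated = (dose_wave >= 0) & (dose_wave < w)  # effect lags one wave
            lp = alpha + outcome_lp + person_u + np.where(treated, theta, 0.0)
            sev[:, w] = rng.random(n) < expit(lp)
            tot[:, w] = _sample_totals(rng, sev[:, w], inst)
        severe[inst] = sev
        totals[inst] = tot

    # --- assemble long table ---
    pid = np.repeat(np.arange(1, n + 1), n_waves)
    wave = np.tile(np.arange(n_waves), n)
    keep = completed.ravel()
    month_arr = np.tile(np.array(months, dtype=object), n)

    dose_wave_rep = np.repeat(dose_wave, n_waves)
    vaccinated_ever = (dose_wave_rep >= 0) & (dose_wave_rep <= wave)
    dose_date_rep = np.repeat(dose_date, n_waves)
    first_dose = np.where(vaccinated_ever, dose_date_rep, pd.NaT)

    df = pd.DataFrame(
        {
            "participant_id": pid,
            "assessment_month": [m.strftime("%Y-%m-%d") for m in month_arr],
            "vaccinated_ever": vaccinated_ever.astype(int),
            "first_dose_date": [
                d.strftime("%Y-%m-%d") if d is not pd.NaT else ""
                for d in first_dose
            ],
            "gad7_total": totals[Instrument.GAD7].ravel(),
            "phq8_total": totals[Instrument.PHQ8].ravel(),
        }
    )
    for name in list(cfg_confounder_names(cfg)) + list(DESCRIPTIVE_BASELINE):
        df[name] = np.repeat(cols[name], n_waves)
    for name, vals in tu_values.items():
        df[name] = vals.ravel()
    # enrollment severity: wave-1 value, carried as an always-complete covariate
    df["enroll_anxiety_severe"] = np.repeat(
        severe[Instrument.GAD7][:, 0].astype(int), n_waves
    )
    df["enroll_depression_severe"] = np.repeat(
        severe[Instrument.PHQ8][:, 0].astype(int), n_waves
    )

    df = df.loc[keep].reset_index(drop=True)
    df["gad7_total"] = df["gad7_total"].astype("Int64")
    df["phq8_total"] = df["phq8_total"].astype("Int64")
    df["gad7_mod_severe"] = (df["gad7_total"] >= SEVERITY_THRESHOLD).astype("Int64")
    df["phq8_mod_severe"] = (df["phq8_total"] >= SEVERITY_THRESHOLD).astype("Int64")

    truth = {
        "config": cfg.to_dict(),
        "alpha": alpha,
        "true_effect_pre": cfg.true_effect_pre,
        "true_effect_uni": cfg.true_effect_uni,
    }
    cohort = SyntheticCohort(assessments=df, truth=truth)
    if cfg.missing_rate > 0:
        cohort = inject_missingness(
            cohort,
            rate=cfg.missing_rate,
            mechanism=cfg.missing_mechanism,
            seed=int(cfg.seed) + 1_000_003,
            coefs=cfg.missing_coefs,
        )
    return cohort


def cfg_confounder_names(cfg: SyntheticConfig) -> list[str]:
    return [c.name for c in cfg.confounders]


def inject_missingness(
    cohort: SyntheticCohort,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    coefs: Mapping[str, float] | None = None,
) -> SyntheticCohort:
    """Blank outcome totals (never covariates) at the given overall rate.

    Under MAR-on-covariates the per-row missingness log-odds is a linear
    function of the named observed covariates (numeric/binary coding), with
    the intercept calibrated so the expected overall share of blanked scores
    equals ``rate``.  Each instrument's score is blanked independently.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError("rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR"):
        raise ConfigError(f"unknown mechanism {mechanism!r}")
    df = cohort.assessments.copy()
    if rate == 0.0 or df.empty:
        return SyntheticCohort(assessments=df, truth=dict(cohort.truth))

    rng = np.random.default_rng(seed)
    if mechanism == "MCAR" or not coefs:
        p = np.full(len(df), rate)
    else:
        lp = np.zeros(len(df))
        for name, c in coefs.items():
            if name not in df.columns:
                raise ConfigError(f"MAR covariate {name!r} not in assessment table")
            lp += c * pd.to_numeric(df[name], errors="raise").to_numpy(dtype=float)
        lo, hi = -30.0, 30.0
        a = brentq(
            lambda a_: float(np.mean(expit(a_ + lp))) - rate, lo, hi, xtol=1e-12
        )
        p = expit(a + lp)

    for inst in (Instrument.GAD7, Instrument.PHQ8):
        pfx = inst.column_prefix
        miss = rng.random(len(df)) < p
        df.loc[miss, f"{pfx}_total"] = pd.NA
        df.loc[miss, f"{pfx}_mod_severe"] = pd.NA

    truth = dict(cohort.truth)
    truth["missingness"] = {"rate": rate, "mechanism": mechanism}
    return SyntheticCohort(assessments=df, truth=truth)
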