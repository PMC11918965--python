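"""Multiple imputation of missing outcome scores and Rubin's-rules pooling.

Missing GAD-7/PHQ-8 outcome totals are drawn from a Bayesian linear
regression on complete covariates: for each of the m imputations the
residual variance is drawn from its scaled inverse-chi-square posterior,
the coefficients from their normal sampling distribution, and the missing
scores from the posterior predictive, then rounded and clipped to the
instrument range.  Predictive-mean matching is available as an alternative
draw method.  Severity indicators are re-derived from imputed totals
downstream, so one set of completed data serves both the binary models and
the linear models.

Per-imputation estimates are combined with Rubin's rules: pooled point is
the mean, total variance is the within-imputation mean plus the
between-imputation variance inflated by (1 + 1/m), and interval estimates
use the Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design
from .errors import ConfigError, ValidationError
from .instruments import Instrument, SEVERITY_THRESHOLD

#: imputation-model predictors mirroring the published models: demographics,
#: socioeconomic covariates and symptom severity at study enrollment.
DEFAULT_PREDICTORS_ANXIETY = (
    "age_band", "race_ethnicity", "gender", "income", "education",
    "employment", "food_insecurity", "housing_instability",
    "children_in_household", "healthcare_access_barriers",
    "enroll_anxiety_severe",
)
DEFAULT_PREDICTORS_DEPRESSION = DEFAULT_PREDICTORS_ANXIETY[:-1] + (
    "enroll_depression_severe",
)


@dataclass
class ImputationSpec:
    """Configuration of one outcome's imputation model."""

    outcome_col: str = "outcome_gad7"
    instrument: Instrument = Instrument.GAD7
    predictors: Sequence[str] = DEFAULT_PREDICTORS_ANXIETY
    m: int = 20
    seed: int = 0
    method: str = "norm"  # posterior-predictive draws; or "pmm"
    pmm_donors: int = 5

    def __post_init__(self):
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.method not in ("norm", "pmm"):
            raise ConfigError(f"unknown imputation method {self.method!r}")
        self.instrument = Instrument(self.instrument)


def impute(person_trials: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Return m completed copies of the person-trial table.

    Observed outcomes are identical across imputations; only originally
    missing cells vary.  Predictors must be complete (the analytic set is
    restricted to confounder-complete records upstream).  Per-imputation
    seeds are derived as ``seed + imputation_index`` for reproducibility.
    """
    col = spec.outcome_col
    if col not in person_trials.columns:
        raise ValidationError(f"outcome column {col!r} not in table")
    y_all = pd.to_numeric(person_trials[col], errors="coerce").to_numpy(dtype=float)
    miss = np.isnan(y_all)
    if not miss.any():
        return [person_trials.copy() for _ in range(spec.m)]

    X, _ = build_design(person_trials, list(spec.predictors))
    X_obs, y_obs, X_mis = X[~miss], y_all[~miss], X[miss]
    n, k = X_obs.shape
    if n <= k:
        raise ValidationError("too few observed outcomes to fit the imputation model")

    XtX = X_obs.T @ X_obs
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    rss = float(resid @ resid)
    dof = n - k
    chol = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(k))
    lo, hi = 0, spec.instrument.max_total

    completed: list[pd.DataFrame] = []
    for j in range(1, spec.m + 1):
        rng = np.random.default_rng(spec.seed + j)
        sigma2 = rss / rng.chisquare(dof)
        beta_star = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(k))
        if spec.method == "norm":
            draws = X_mis @ beta_star + rng.normal(0.0, np.sqrt(sigma2), size=X_mis.shape[0])
        else:  # predictive-mean matching on beta_star predictions
            pred_obs = X_obs @ beta_star
            pred_mis = X_mis @ beta_star
            order = np.argsort(pred_obs, kind="stable")
            pos = np.searchsorted(pred_obs[order], pred_mis)
            draws = np.empty(len(pred_mis))
            for i, p in enumerate(pos):
                lo_i = max(0, p - spec.pmm_donors)
                hi_i = min(n, p + spec.pmm_donors)
                donor = rng.integers(lo_i, hi_i)
                draws[i] = y_obs[order[donor]]
        vals = np.clip(np.rint(draws), lo, hi).astype(np.int64)
        out = person_trials.copy()
        filled = out[col].copy()
        filled.iloc[np.flatnonzero(miss)] = vals
        out[col] = filled.astype("Int64")
        completed.append(out)
    return completed


def severity_from_totals(totals: pd.Series, threshold: int = SEVERITY_THRESHOLD) -> pd.Series:
    t = pd.to_numeric(totals, errors="coerce")
    return (t >= threshold).astype("Int64").where(t.notna())


@dataclass
class PooledEstimate:
    """Rubin combination of m per-imputation estimates on one scale."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int
    ci95: tuple[float, float]

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def rubin_pool(
    points: Sequence[float],
    variances: Sequence[float],
    dfcom: float | None = None,
) -> PooledEstimate:
    """Pool m estimates: mean point, W + (1 + 1/m) B total variance, 95% CI
    from a t distribution with Barnard-Rubin degrees of freedom.

    With m = 1, or when all points coincide, the between-imputation variance
    is exactly 0 and the pooled estimate reproduces the (first) input
    bitwise, so a no-missing-data run is identical to the complete-data
    analysis.
    """
    pts = np.asarray(points, dtype=float)
    vrs = np.asarray(variances, dtype=float)
    if pts.shape != vrs.shape or pts.ndim != 1 or len(pts) < 1:
        raise ValidationError("points and variances must be equal-length 1-d sequences")
    m = len(pts)

    identical = bool(np.all(pts == pts[0]) and np.all(vrs == vrs[0]))
    if m == 1 or identical:
        point, W, B = float(pts[0]), float(vrs[0]), 0.0
    else:
        point = float(np.mean(pts))
        W = float(np.mean(vrs))
        B = float(np.var(pts, ddof=1))
    T = W + (1.0 + 1.0 / m) * B

    if B == 0.0 or T == 0.0:
        df = float(dfcom) if dfcom is not None else np.inf
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df_old = (m - 1) / lam**2
        if dfcom is not None and np.isfinite(dfcom):
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old

    se = float(np.sqrt(T))
    tcrit = stats.norm.ppf(0.975) if not np.isfinite(df) else stats.t.ppf(0.975, df)
    ci = (point - tcrit * se, point + tcrit * se)
    return PooledEstimate(
        point=point, within_var=W, between_var=B, total_var=T,
        df=float(df), m=m, ci95=ci,
    )


def model_bic(loglik: float, k_params: int, n_obs: int) -> float:
    """Bayesian information criterion: k ln(n) - 2 loglik."""
    if n_obs < 1:
        raise ValidationError("n_obs must be positive")
    return k_params * float(np.log(n_obs)) - 2.0 * float(loglik)
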