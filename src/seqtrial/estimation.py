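"""Intention-to-treat-analog models over the person-trial table.

The primary model is a pooled logistic regression of the dichotomized
outcome (score >= 10) on vaccination status and the adjustment set,
stratified by vaccine era, with a cluster-robust sandwich variance over
participants because a participant may contribute up to K person-trials.
Descriptive 2x2 odds ratios (Woolf intervals), Wald binomial prevalence
intervals, subgroup fits among those with moderate-to-severe symptoms at
time zero, a Wald chi-square test of effect heterogeneity across eras, and
a random-intercept linear mixed model for the continuous score complete the
estimator set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import build_design
from .errors import EstimationError, ValidationError
from .instruments import SEVERITY_THRESHOLD

Z95 = stats.norm.ppf(0.975)

#: adjustment set of the primary models: minimum sufficient set from the
#: study's a-priori causal diagram, taken as given.
DEFAULT_ADJUSTMENT_ANXIETY = (
    "healthcare_access_barriers", "age_band", "anxiety_t0", "education",
    "employment", "gender", "housing_instability", "food_insecurity",
    "susceptibility",
)
DEFAULT_ADJUSTMENT_DEPRESSION = (
    "healthcare_access_barriers", "age_band", "depression_t0", "education",
    "employment", "gender", "housing_instability", "food_insecurity",
    "susceptibility",
)


@dataclass
class ModelSpec:
    """One outcome model: which score, which covariates, which era stratum."""

    outcome: str = "anxiety_mod_severe"  # or depression_mod_severe / gad7_total / phq8_total
    treatment: str = "treatment"
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT_ANXIETY
    era: str = "both"  # "preuniversal" | "universal" | "both"
    cluster: str = "participant_id"
    threshold: int = SEVERITY_THRESHOLD

    @property
    def outcome_total_col(self) -> str:
        return "outcome_gad7" if "anxiety" in self.outcome or "gad7" in self.outcome else "outcome_phq8"

    @property
    def binary(self) -> bool:
        return self.outcome.endswith("_mod_severe")


@dataclass
class EffectEstimate:
    """A treatment effect with model-based and cluster-robust uncertainty."""

    scale: str  # "log_odds" | "score_points"
    point: float
    se_model: float
    se_robust: float
    ci95: tuple[float, float]
    n_person_trials: int
    n_participants: int
    era: str = "both"

    @property
    def odds_ratio(self) -> float:
        if self.scale != "log_odds":
            raise ValidationError("odds_ratio only defined on the log-odds scale")
        return float(np.exp(self.point))

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a/b treated with/without outcome, c/d untreated."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be nonnegative")


def prevalence(count: int, denom: int) -> tuple[float, float, float]:
    """Percentage with a Wald binomial 95% CI, as printed in cohort tables."""
    if denom <= 0:
        raise ValidationError("denominator must be positive")
    if not (0 <= count <= denom):
        raise ValidationError("count must be between 0 and denominator")
    p = count / denom
    half = Z95 * np.sqrt(p * (1 - p) / denom)
    return (100.0 * p, 100.0 * (p - half), 100.0 * (p + half))


def crude_or(tab: ContingencyTable) -> EffectEstimate:
    """Closed-form 2x2 odds ratio with a Woolf log-scale interval.

    Zero cells raise (no continuity correction is applied by default).
    """
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    if min(a, b, c, d) == 0:
        raise EstimationError("zero cell in 2x2 table; odds ratio undefined")
    point = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    ci = (point - Z95 * se, point + Z95 * se)
    return EffectEstimate(
        scale="log_odds", point=point, se_model=se, se_robust=se, ci95=ci,
        n_person_trials=a + b + c + d, n_participants=a + b + c + d, era="both",
    )


@dataclass
class LogisticFit:
    """A fitted pooled logistic model with the pieces the sandwich needs."""

    params: np.ndarray
    names: list[str]
    cov_model: np.ndarray
    X: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    cluster_ids: np.ndarray
    loglik: float

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_ids))

    @property
    def dfcom(self) -> int:
        return self.n_obs - len(self.params)


def robust_cluster_variance(fit: LogisticFit, cluster_ids: np.ndarray | None = None,
                            correction: str = "CR0") -> np.ndarray:
    """Cluster sandwich A^-1 B A^-1 with scores summed within clusters.

    CR0 applies no small-sample factor; CR1 multiplies by G/(G-1).  With one
    observation per cluster CR0 reduces to the heteroskedasticity-robust
    (HC0) estimator.
    """
    ids = fit.cluster_ids if cluster_ids is None else np.asarray(cluster_ids)
    X, y, mu = fit.X, fit.y, fit.mu
    k = X.shape[1]
    codes, groups = pd.factorize(ids)
    G = len(groups)
    if G < k:
        warnings.warn(
            f"only {G} clusters for {k} parameters; sandwich variance unreliable",
            stacklevel=2,
        )
    scores = X * (y - mu)[:, None]
    S = np.zeros((G, k))
    np.add.at(S, codes, scores)
    B = S.T @ S
    A_inv = fit.cov_model  # inverse Fisher information
    V = A_inv @ B @ A_inv
    if correction == "CR1":
        V = V * (G / (G - 1.0))
    elif correction != "CR0":
        raise ValidationError(f"unknown correction {correction!r}")
    return V


def fit_logistic(
    df: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    treatment_col: str,
    adjustment: Sequence[str],
    cluster_col: str = "participant_id",
    correction: str = "CR0",
) -> tuple[EffectEstimate, LogisticFit]:
    """Maximum-likelihood logistic fit (IRLS, tol 1e-8, <=100 iterations)
    of the binary outcome on treatment + adjustment, with CR0 cluster
    sandwich standard errors for the treatment coefficient."""
    y = pd.to_numeric(pd.Series(outcome), errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("binary outcome contains missing values; impute first")
    X, names = build_design(df, [treatment_col] + list(adjustment))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except Exception as exc:  # noqa: BLE001 - surface as estimation failure
            raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise EstimationError("logistic fit did not converge in 100 IRLS iterations")
    params = np.asarray(res.params, dtype=float)
    if np.max(np.abs(params)) > 30:
        worst = names[int(np.argmax(np.abs(params)))]
        raise EstimationError(f"quasi-separation detected (diverging coefficient: {worst})")

    mu = np.asarray(res.fittedvalues, dtype=float)
    w = mu * (1 - mu)
    A = X.T @ (w[:, None] * X)
    cov_model = np.linalg.pinv(A)
    fit = LogisticFit(
        params=params, names=names, cov_model=cov_model, X=X, y=y, mu=mu,
        cluster_ids=df[cluster_col].to_numpy(), loglik=float(res.llf),
    )
    V = robust_cluster_variance(fit, correction=correction)
    ti = names.index(treatment_col)
    point = float(params[ti])
    se_m = float(np.sqrt(cov_model[ti, ti]))
    se_r = float(np.sqrt(V[ti, ti]))
    est = EffectEstimate(
        scale="log_odds", point=point, se_model=se_m, se_robust=se_r,
        ci95=(point - Z95 * se_r, point + Z95 * se_r),
        n_person_trials=len(df), n_participants=int(df[cluster_col].nunique()),
    )
    return est, fit


def fit_pooled_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    correction: str = "CR0",
) -> tuple[EffectEstimate, LogisticFit]:
    """Era-stratified pooled logistic fit on one completed dataset."""
    df = data if spec.era == "both" else data[data["era"] == spec.era]
    if df.empty:
        raise EstimationError(f"no person-trials in era {spec.era!r}")
    if spec.binary:
        totals = pd.to_numeric(df[spec.outcome_total_col], errors="coerce")
        y = (totals >= spec.threshold).astype(float)
        if totals.isna().any():
            raise ValidationError("binary outcome contains missing values; impute first")
    else:
        y = pd.to_numeric(df[spec.outcome_total_col], errors="coerce")
    est, fit = fit_logistic(
        df, y, spec.treatment, list(spec.adjustment), spec.cluster, correction
    )
    est.era = spec.era
    return est, fit


def subgroup_analysis(
    data: pd.DataFrame,
    spec: ModelSpec,
    condition_col: str,
    correction: str = "CR0",
) -> tuple[EffectEstimate, LogisticFit]:
    """Fit among person-trials with moderate-to-severe symptoms at time zero.

    The conditioning severity covariate is dropped from the adjustment set
    (it is constant within the subgroup)."""
    if condition_col not in data.columns:
        raise ValidationError(f"subgroup condition column {condition_col!r} missing")
    sub = data[pd.to_numeric(data[condition_col], errors="coerce") == 1]
    if sub.empty:
        raise EstimationError(f"empty subgroup: {condition_col} == 1")
    sub_spec = ModelSpec(
        outcome=spec.outcome, treatment=spec.treatment,
        adjustment=[c for c in spec.adjustment if c != condition_col],
        era=spec.era, cluster=spec.cluster, threshold=spec.threshold,
    )
    return fit_pooled_logistic(sub, sub_spec, correction)


def wald_heterogeneity(est_pre: EffectEstimate, est_uni: EffectEstimate) -> tuple[float, float]:
    """Wald chi-square (df=1) test of equality of two stratum log-ORs."""
    v = est_pre.se_robust**2 + est_uni.se_robust**2
    if v <= 0:
        raise EstimationError("zero variances; Wald statistic undefined")
    W = (est_pre.point - est_uni.point) ** 2 / v
    p = float(stats.chi2.sf(W, df=1))
    return float(W), p


def fit_random_intercept_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
) -> EffectEstimate:
    """REML linear mixed model of the continuous score on treatment +
    adjustment with a participant random intercept; the treatment
    coefficient is in score points."""
    df = data if spec.era == "both" else data[data["era"] == spec.era]
    if df.empty:
        raise EstimationError(f"no person-trials in era {spec.era!r}")
    y = pd.to_numeric(df[spec.outcome_total_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("continuous outcome contains missing values; impute first")
    X, names = build_design(df, [spec.treatment] + list(spec.adjustment))
    groups = df[spec.cluster].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        except Exception as exc:  # noqa: BLE001
            raise EstimationError(f"mixed model failed: {exc}") from exc
    if not res.converged:
        raise EstimationError(
            f"mixed model did not converge (random-intercept var {float(res.cov_re.iloc[0, 0]):.3g}, "
            f"residual var {float(res.scale):.3g})"
        )
    ti = names.index(spec.treatment)
    point = float(res.params[ti])
    se = float(res.bse[ti])
    return EffectEstimate(
        scale="score_points", point=point, se_model=se, se_robust=se,
        ci95=(point - Z95 * se, point + Z95 * se),
        n_person_trials=len(df), n_participants=int(df[spec.cluster].nunique()),
        era=spec.era,
    )
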