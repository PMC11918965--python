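import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seqtrial import (
    ContingencyTable,
    EstimationError,
    ModelSpec,
    ValidationError,
    crude_or,
    fit_pooled_logistic,
    fit_random_intercept_lmm,
    prevalence,
    robust_cluster_variance,
    subgroup_analysis,
    wald_heterogeneity,
)
from seqtrial.estimation import EffectEstimate, fit_logistic

from _oracles import expand_2x2


@pytest.mark.parametrize(
    "count, denom, pct, lo, hi",
    [
        (1171, 4846, 24.2, 23.0, 25.4),   # printed full-cohort interval
        (532, 3194, 16.7, 15.4, 17.9),
        (840, 1292, 65.0, 62.4, 67.6),    # printed subgroup interval
        (361, 656, 55.0, 51.2, 58.8),
        (0, 50, 0.0, 0.0, 0.0),
    ],
)
def test_prevalence_matches_printed_intervals(count, denom, pct, lo, hi):
    p, l, h = prevalence(count, denom)
    assert round(p, 1) == pct
    assert round(l, 1) == pytest.approx(lo, abs=0.1)
    assert round(h, 1) == pytest.approx(hi, abs=0.1)


def test_prevalence_rejects_bad_input():
    with pytest.raises(ValidationError):
        prevalence(1, 0)
    with pytest.raises(ValidationError):
        prevalence(5, 4)


def test_crude_or_closed_form():
    assert crude_or(ContingencyTable(10, 10, 10, 10)).odds_ratio == pytest.approx(1.0)
    assert crude_or(ContingencyTable(20, 10, 10, 20)).odds_ratio == pytest.approx(4.0)
    # printed full-cohort preuniversal anxiety counts: ad/bc differs from the
    # published model-based OR, so only the closed form is asserted
    est = crude_or(ContingencyTable(532, 2662, 1171, 3675))
    assert est.odds_ratio == pytest.approx(0.627, abs=0.001)
    with pytest.raises(EstimationError):
        crude_or(ContingencyTable(0, 5, 5, 5))


def test_logistic_reproduces_2x2_log_or():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a, b, c, d = rng.integers(3, 60, size=4)
        df = expand_2x2(a, b, c, d)
        est, _ = fit_logistic(df, df["outcome"], "treatment", [])
        assert est.point == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)


def test_singleton_clusters_reduce_to_hc0():
    rng = np.random.default_rng(4)
    n = 300
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "treatment": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
        }
    )
    y = (rng.random(n) < 0.3 + 0.2 * df["treatment"]).astype(int)
    est, fit = fit_logistic(df, y, "treatment", ["x"])
    V = robust_cluster_variance(fit)
    res = sm.GLM(fit.y, fit.X, family=sm.families.Binomial()).fit(cov_type="HC0")
    np.testing.assert_allclose(V, res.cov_params(), rtol=1e-6)


def test_cluster_sandwich_matches_statsmodels_cluster():
    rng = np.random.default_rng(5)
    n, g = 600, 120
    df = pd.DataFrame(
        {
            "participant_id": rng.integers(0, g, n),
            "treatment": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
        }
    )
    y = (rng.random(n) < 0.4 + 0.15 * df["treatment"]).astype(int)
    est, fit = fit_logistic(df, y, "treatment", ["x"])
    V = robust_cluster_variance(fit)
    res = sm.GLM(fit.y, fit.X, family=sm.families.Binomial()).fit(
        cov_type="cluster",
        cov_kwds={"groups": df["participant_id"].to_numpy(), "use_correction": False},
    )
    np.testing.assert_allclose(V, res.cov_params(), rtol=1e-5)
    # CR1 applies the G/(G-1) factor over the observed clusters
    G = df["participant_id"].nunique()
    V1 = robust_cluster_variance(fit, correction="CR1")
    np.testing.assert_allclose(V1, V * G / (G - 1), rtol=1e-12)


def test_duplicating_clusters_halves_model_variance_not_robust():
    rng = np.random.default_rng(6)
    n = 200
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "treatment": rng.integers(0, 2, n),
        }
    )
    y = (rng.random(n) < 0.3 + 0.25 * df["treatment"]).astype(int)
    df["y"] = y
    est1, fit1 = fit_logistic(df, df["y"], "treatment", [])
    dup = pd.concat([df, df], ignore_index=True)
    est2, fit2 = fit_logistic(dup, dup["y"], "treatment", [])
    assert est2.point == pytest.approx(est1.point, abs=1e-7)
    # model-based variance halves; the cluster sandwich sees no new information
    assert est2.se_model**2 == pytest.approx(est1.se_model**2 / 2, rel=1e-5)
    assert est2.se_robust == pytest.approx(est1.se_robust, rel=1e-5)


def test_separation_raises_with_offending_column():
    df = pd.DataFrame(
        {
            "participant_id": np.arange(20),
            "treatment": [0] * 10 + [1] * 10,
        }
    )
    y = df["treatment"]  # perfect separation by treatment
    with pytest.raises(EstimationError, match="treatment|converge"):
        fit_logistic(df, y, "treatment", [])


def test_missing_outcome_rejected():
    df = pd.DataFrame(
        {
            "participant_id": [1, 2, 3],
            "treatment": [0, 1, 0],
            "era": ["preuniversal"] * 3,
            "outcome_gad7": pd.array([5, pd.NA, 12], dtype="Int64"),
        }
    )
    with pytest.raises(ValidationError, match="impute"):
        fit_pooled_logistic(df, ModelSpec(outcome="anxiety_mod_severe", adjustment=[]))


def test_subgroup_filters_rows_and_drops_condition():
    rng = np.random.default_rng(7)
    n = 500
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "treatment": rng.integers(0, 2, n),
            "era": "preuniversal",
            "anxiety_t0": rng.integers(0, 2, n),
            "outcome_gad7": pd.array(rng.integers(0, 22, n), dtype="Int64"),
        }
    )
    spec = ModelSpec(outcome="anxiety_mod_severe", adjustment=["anxiety_t0"],
                     era="preuniversal")
    est, fit = subgroup_analysis(df, spec, "anxiety_t0")
    assert est.n_person_trials == int((df["anxiety_t0"] == 1).sum())
    assert "anxiety_t0" not in fit.names
    with pytest.raises(EstimationError, match="empty subgroup"):
        subgroup_analysis(df.assign(anxiety_t0=0), spec, "anxiety_t0")


def test_wald_heterogeneity_values():
    def _e(point, var):
        se = float(np.sqrt(var))
        return EffectEstimate(
            scale="log_odds", point=point, se_model=se, se_robust=se,
            ci95=(point - 1.96 * se, point + 1.96 * se),
            n_person_trials=10, n_participants=10,
        )

    W, p = wald_heterogeneity(_e(0.4, 0.1), _e(0.4, 0.2))
    assert W == 0.0 and p == 1.0
    W, p = wald_heterogeneity(_e(0.0, 0.25), _e(1.0, 0.25))
    assert W == pytest.approx(2.0)
    assert p == pytest.approx(0.1573, abs=2e-4)
    with pytest.raises(EstimationError):
        wald_heterogeneity(_e(0.1, 0.0), _e(0.2, 0.0))


def test_lmm_with_singleton_groups_matches_ols():
    rng = np.random.default_rng(8)
    n = 400
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),  # one observation per participant
            "treatment": rng.integers(0, 2, n),
            "era": "preuniversal",
            "x": rng.normal(size=n),
            "outcome_gad7": pd.array(
                np.clip(np.round(10 - 1.2 * rng.integers(0, 2, n) + rng.normal(0, 3, n)), 0, 21
                        ).astype(int), dtype="Int64"),
        }
    )
    spec = ModelSpec(outcome="gad7_total", adjustment=["x"], era="preuniversal")
    est = fit_random_intercept_lmm(df, spec)
    X = np.column_stack([np.ones(n), df["treatment"], df["x"]])
    ols = sm.OLS(df["outcome_gad7"].astype(float), X).fit()
    assert est.point == pytest.approx(ols.params.iloc[1], abs=1e-4)
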