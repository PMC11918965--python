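from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seqtrial.synthetic import Covariate, SyntheticConfig, simulate_cohort

#: the single-binary-confounder generating condition used by the recovery
#: and calibration studies
ONE_CONFOUNDER = (
    Covariate(
        name="susceptibility",
        levels=(0, 1),
        probs=(0.79, 0.21),
        outcome_coefs=(0.0, 0.8),
        uptake_coefs=(0.0, 0.5),
    ),
)


def one_confounder_config(**kwargs) -> SyntheticConfig:
    kwargs.setdefault("confounders", ONE_CONFOUNDER)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant cohort with default (two-confounder) structure and
    7% MAR missingness; shared across read-only tests."""
    return simulate_cohort(SyntheticConfig(n_participants=400, seed=20201201))


@pytest.fixture(scope="session")
def complete_cohort():
    """A 400-participant cohort with no missing outcomes."""
    return simulate_cohort(
        SyntheticConfig(n_participants=400, seed=20210419, missing_rate=0.0)
    )


def toy_assessments(rows: list[dict]) -> pd.DataFrame:
    """Hand-written long-format fixture; fills structural defaults."""
    df = pd.DataFrame(rows)
    for col, default in (
        ("first_dose_date", ""),
        ("gad7_total", pd.NA),
        ("phq8_total", pd.NA),
        ("gad7_mod_severe", pd.NA),
        ("phq8_mod_severe", pd.NA),
        ("education", "c"),
    ):
        if col not in df.columns:
            df[col] = default
    for col in ("gad7_total", "phq8_total", "gad7_mod_severe", "phq8_mod_severe",
                "vaccinated_ever"):
        df[col] = df[col].astype("Int64")
    return df
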