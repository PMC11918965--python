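"""Design-matrix construction shared by the imputation and estimation stages.

Categorical covariates are dummy-coded against a reference level; reference
levels default to the category conventions of the cohort the pipeline
emulates (largest group as reference), falling back to the most frequent
observed level for unknown columns.  Numeric and 0/1 columns enter as-is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

#: preferred reference levels (used when present in the data)
REFERENCE_LEVELS = {
    "age_band": "18-49",
    "gender": "cis_male",
    "race_ethnicity": "white_nh",
    "income": "lt_50k",
    "education": "college_grad",
    "employment": "employed",
    "housing_instability": 0,
    "food_insecurity": 0,
}


def is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s.dtype) or pd.api.types.is_bool_dtype(s.dtype)


def build_design(
    df: pd.DataFrame,
    columns: list[str],
    add_intercept: bool = True,
    references: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Return (X, column names).  Raises if a requested column is missing or
    contains missing values (the analytic set is confounder-complete)."""
    refs = dict(REFERENCE_LEVELS)
    if references:
        refs.update(references)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("intercept")
    for col in columns:
        if col not in df.columns:
            raise ValidationError(f"design column {col!r} not in table")
        s = df[col]
        if s.isna().any():
            raise ValidationError(f"design column {col!r} has missing values")
        if is_numeric(s):
            blocks.append(s.to_numpy(dtype=float).reshape(-1, 1))
            names.append(col)
        else:
            levels = sorted(pd.unique(s.astype(str)))
            ref = refs.get(col)
            ref = str(ref) if ref is not None and str(ref) in levels else s.astype(str).mode().iloc[0]
            for lev in levels:
                if lev == ref:
                    continue
                blocks.append((s.astype(str) == lev).to_numpy(dtype=float).reshape(-1, 1))
                names.append(f"{col}[{lev}]")
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return X, names
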