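"""Scoring of the GAD-7 and PHQ-8 mental-health screeners.

The GAD-7 (7 items) screens for generalized anxiety and the PHQ-8 (8 items)
for depression.  Each item is scored 0-3, so totals range 0-21 (GAD-7) and
0-24 (PHQ-8).  A total of 10 or more denotes moderate-to-severe symptoms,
the dichotomous outcome used throughout the pipeline.

Partially answered instruments are not prorated: any missing item makes the
total missing.  Missing totals are handled downstream by multiple imputation
at the score level, never at the item level.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: total score at or above which symptoms are classed moderate-to-severe
SEVERITY_THRESHOLD = 10


class Instrument(str, Enum):
    GAD7 = "GAD7"
    PHQ8 = "PHQ8"

    @property
    def n_items(self) -> int:
        return 7 if self is Instrument.GAD7 else 8

    @property
    def max_total(self) -> int:
        return 3 * self.n_items

    @property
    def column_prefix(self) -> str:
        return "gad7" if self is Instrument.GAD7 else "phq8"


@dataclass(frozen=True)
class InstrumentResponse:
    """One participant's answers to a single instrument."""

    instrument: Instrument
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        inst = Instrument(self.instrument)
        object.__setattr__(self, "instrument", inst)
        items = tuple(self.items)
        if len(items) != inst.n_items:
            raise ValidationError(
                f"{inst.value} expects {inst.n_items} items, got {len(items)}"
            )
        for i, v in enumerate(items):
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 3):
                raise ValidationError(
                    f"{inst.value} item {i + 1} out of range: {v!r} (valid: 0..3)"
                )
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class InstrumentScore:
    instrument: Instrument
    total: int
    severe: bool


def classify_severity(
    total: int, instrument: Instrument, threshold: int = SEVERITY_THRESHOLD
) -> bool:
    """Return True iff ``total`` meets the moderate-to-severe cut (>= threshold)."""
    inst = Instrument(instrument)
    if not (0 <= total <= inst.max_total):
        raise ValidationError(
            f"{inst.value} total {total} outside range 0..{inst.max_total}"
        )
    return total >= threshold


def score_instrument(resp: InstrumentResponse) -> InstrumentScore:
    """Sum the item scores and classify severity."""
    total = int(sum(resp.items))
    return InstrumentScore(
        instrument=resp.instrument,
        total=total,
        severe=classify_severity(total, resp.instrument),
    )


def score_frame(
    df: pd.DataFrame,
    instrument: Instrument,
    threshold: int = SEVERITY_THRESHOLD,
) -> pd.DataFrame:
    """Derive total and severity columns for one instrument on a long table.

    Accepts item columns (``gad7_1..gad7_7`` / ``phq8_1..phq8_8``), a
    pre-computed total column (``gad7_total`` / ``phq8_total``), or both.
    Any missing item makes the row's total missing.  When both items and a
    total are present the total must equal the item sum.

    Returns a copy of ``df`` with ``<prefix>_total`` (nullable integer) and
    ``<prefix>_mod_severe`` (nullable 0/1) columns filled in.
    """
    inst = Instrument(instrument)
    prefix = inst.column_prefix
    item_cols = [f"{prefix}_{i}" for i in range(1, inst.n_items + 1)]
    total_col, severe_col = f"{prefix}_total", f"{prefix}_mod_severe"
    out = df.copy()

    have_items = all(c in out.columns for c in item_cols)
    have_total = total_col in out.columns
    if not have_items and not have_total:
        raise ValidationError(
            f"need either {item_cols[0]}..{item_cols[-1]} or {total_col}"
        )

    if have_items:
        items = out[item_cols].astype("Float64")
        bad = ((items < 0) | (items > 3)).any(axis=1)
        if bad.any():
            idx = out.index[bad][0]
            raise ValidationError(
                f"out-of-range item score for {prefix} at row {idx}"
            )
        item_sum = items.sum(axis=1, skipna=False).round().astype("Int64")
        if have_total:
            given = out[total_col].astype("Int64")
            both = item_sum.notna() & given.notna()
            if (item_sum[both] != given[both]).any():
                idx = out.index[both][item_sum[both] != given[both]][0]
                raise ValidationError(
                    f"{total_col} disagrees with item sum at row {idx}"
                )
            total = given.where(given.notna(), item_sum)
        else:
            total = item_sum
    else:
        total = out[total_col].astype("Int64")

    if ((total < 0) | (total > inst.max_total)).any():
        idx = out.index[(total < 0) | (total > inst.max_total)][0]
        raise ValidationError(
            f"{total_col} outside 0..{inst.max_total} at row {idx}"
        )

    out[total_col] = total
    out[severe_col] = (total >= threshold).astype("Int64").where(total.notna())
    return out
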