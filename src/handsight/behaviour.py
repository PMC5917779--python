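"""Prosthesis usage scores from questionnaire data.

One-handers rate how often they use their prosthesis in 27 everyday
activities (Motor Activity Log, MAL: 0 = never, 1 = sometimes, 2 = very
often) and how long they typically wear it (ordinal 0-5, never to daily
> 8 h).  Controls complete the analogous prosthesis observation log (POL)
about prostheses they see being used.  The composite usage (or observation)
score is the sum of the two z-transformed measures, standardized within the
group that answered the questionnaire.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["mal_fraction", "composite_score", "usage_table"]

logger = logging.getLogger(__name__)

N_MAL_ITEMS = 27
MAX_ITEM_RATING = 2
WEAR_TIME_MAX = 5


def mal_fraction(items) -> float:
    """Normalize 27 activity ratings to a [0, 1] usage fraction.

    The item sum is divided by the maximum possible score (27 items x
    rating 2 = 54).
    """
    arr = np.asarray(items)
    if arr.shape != (N_MAL_ITEMS,):
        raise ValueError(f"expected exactly {N_MAL_ITEMS} items, got shape {arr.shape}")
    if not np.all(np.isin(arr, [0, 1, 2])):
        raise ValueError("item ratings must be 0, 1 or 2")
    return float(arr.sum()) / (N_MAL_ITEMS * MAX_ITEM_RATING)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance vector; cohort is degenerate")
    return (v - v.mean()) / sd


def composite_score(mal_fractions, wear_times) -> np.ndarray:
    """Composite usage score: z(MAL fraction) + z(wear time) per subject.

    Each measure is z-transformed over the cohort with the sample (n-1)
    standard deviation, then the two z-values are summed. The cohort mean of
    the result is 0 by construction.
    """
    mal = np.asarray(mal_fractions, dtype=float).ravel()
    wear = np.asarray(wear_times, dtype=float).ravel()
    if mal.size != wear.size:
        raise ValueError("mal_fractions and wear_times must have equal length")
    if mal.size < 2:
        raise ValueError("need a cohort of at least 2 subjects")
    if np.any(mal < 0) or np.any(mal > 1):
        raise ValueError("MAL fractions must lie in [0, 1]")
    if np.any(wear < 0) or np.any(wear > WEAR_TIME_MAX):
        raise ValueError(f"wear times must lie in [0, {WEAR_TIME_MAX}]")
    return _zscore(mal) + _zscore(wear)


def usage_table(behaviour: pd.DataFrame) -> pd.DataFrame:
    """Attach per-subject usage/observation composites to a behavioural table.

    Standardization is done within group: one-handers' MAL and wear time are
    z-transformed over the one-hander cohort, controls' observation measures
    over the controls (the two questionnaires are distinct instruments).
    Subjects with missing questionnaire data (NaN in any mal item or
    wear_time) are dropped with a warning.

    Expects columns ``subject_id``, ``group`` (one_hander / control),
    ``mal_01`` ... ``mal_27`` and ``wear_time``; returns a copy with
    ``mal_fraction`` and ``usage_score`` columns, dropped subjects excluded.
    """
    item_cols = [f"mal_{i:02d}" for i in range(1, N_MAL_ITEMS + 1)]
    missing_cols = [c for c in item_cols + ["subject_id", "group", "wear_time"]
                    if c not in behaviour.columns]
    if missing_cols:
        raise ValueError(f"behavioural table lacks columns: {missing_cols}")

    df = behaviour.copy()
    incomplete = df[item_cols + ["wear_time"]].isna().any(axis=1)
    if incomplete.any():
        dropped = df.loc[incomplete, "subject_id"].tolist()
        warnings.warn(
            f"dropping {len(dropped)} subject(s) with incomplete "
            f"questionnaires: {dropped}", stacklevel=2)
        logger.info("dropped incomplete questionnaires: %s", dropped)
        df = df.loc[~incomplete].copy()

    df["mal_fraction"] = [
        mal_fraction(row) for row in df[item_cols].to_numpy(dtype=int)
    ]
    df["usage_score"] = np.nan
    for grp, idx in df.groupby("group").groups.items():
        sub = df.loc[idx]
        if len(sub) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 complete subjects")
        df.loc[idx, "usage_score"] = composite_score(
            sub["mal_fraction"], sub["wear_time"])
    return df
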