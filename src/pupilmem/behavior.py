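"""Recall-error computation and behavioural exclusion rules.

Three screens are applied before model fitting:

1. *Chance-level participants*: a participant whose mean absolute recall
   error is 75 degrees or more (the expectation under pure guessing is 90)
   performed at chance on the memory test and is excluded entirely.
2. *Misclassified study trials*: trials where the study-phase item
   classification was wrong are dropped; a participant left with fewer than
   a minimum number of trials per condition (default 10) is excluded from
   model fitting.
3. *Outlier parameter estimates*: condition-wise mixture estimates more
   than 2.5 sample standard deviations from their condition mean are
   flagged for sensitivity analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .angles import wrap_signed_deg

CHANCE_MEAN_ABS_ERROR_DEG = 75.0


def circular_error(response_deg, target_deg):
    """Signed circular recall error ``response - target`` in (-180, 180].

    Antisymmetric up to the +180 boundary convention, and invariant to
    adding multiples of 360 to either argument.  Non-finite inputs raise.
    """
    r = np.asarray(response_deg, dtype=float)
    t = np.asarray(target_deg, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise ValueError("angles must be finite")
    return wrap_signed_deg(r - t)


def exclude_chance_participants(
    trials: pd.DataFrame,
    threshold_deg: float = CHANCE_MEAN_ABS_ERROR_DEG,
    error_col: str = "error_deg",
    participant_col: str = "participant",
):
    """Drop participants whose mean absolute error is at/above chance level.

    The threshold is inclusive: a mean absolute error of exactly
    ``threshold_deg`` excludes the participant.

    Returns
    -------
    retained : pd.DataFrame
        Trials of retained participants.
    report : dict
        ``{"threshold_deg", "excluded", "mean_abs_error"}`` where
        ``excluded`` is the sorted list of excluded participant ids and
        ``mean_abs_error`` maps every participant to their mean |error|.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    mae = (
        trials[error_col]
        .abs()
        .groupby(trials[participant_col])
        .mean()
    )
    excluded = sorted(mae.index[mae >= threshold_deg].tolist())
    retained = trials[~trials[participant_col].isin(excluded)].copy()
    report = {
        "threshold_deg": threshold_deg,
        "excluded": excluded,
        "mean_abs_error": {str(k): float(v) for k, v in mae.items()},
    }
    return retained, report


def filter_classified_trials(
    trials: pd.DataFrame,
    min_per_condition: int = 10,
    classified_col: str = "classified_correct",
    participant_col: str = "participant",
    condition_col: str = "condition",
):
    """Keep only correctly classified study trials; drop sparse participants.

    A participant retaining fewer than ``min_per_condition`` trials in any
    condition is removed from model fitting (their remaining data are too
    few for a stable mixture estimate).

    Returns ``(filtered, excluded_participants)``.
    """
    kept = trials[trials[classified_col].astype(bool)].copy()
    counts = kept.groupby([participant_col, condition_col]).size().unstack(fill_value=0)
    too_few = counts.index[(counts < min_per_condition).any(axis=1)].tolist()
    # participants who lost *all* trials never appear in `counts`
    all_ids = set(trials[participant_col].unique())
    too_few = sorted(set(too_few) | (all_ids - set(counts.index)))
    filtered = kept[~kept[participant_col].isin(too_few)].copy()
    return filtered, too_few


def detect_outlier_estimates(
    estimates: pd.DataFrame,
    k_sd: float = 2.5,
    value_col: str = "value",
    participant_col: str = "participant",
    condition_col: str = "condition",
    ddof: int = 1,
):
    """Flag estimates > ``k_sd`` sample SDs from their condition mean.

    ``estimates`` is long-format: one row per participant x condition with
    the estimate in ``value_col``.  The screen uses the sample (n-1) SD.
    A zero-variance condition yields no outliers and a warning.

    Returns a list of ``(participant, condition)`` tuples.
    """
    flagged = []
    for cond, sub in estimates.groupby(condition_col):
        if len(sub) < 3:
            raise ValueError(
                f"need >= 3 estimates per condition, got {len(sub)} for {cond!r}"
            )
        vals = sub[value_col].to_numpy(dtype=float)
        sd = vals.std(ddof=ddof)
        if sd == 0.0:
            warnings.warn(f"zero-variance estimates in condition {cond!r}")
            continue
        z = np.abs(vals - vals.mean()) / sd
        for pid in sub.loc[z > k_sd, participant_col]:
            flagged.append((pid, cond))
    return flagged
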