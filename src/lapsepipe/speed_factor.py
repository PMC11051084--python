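"""Per-learner speed factors and speed-adjusted threshold classification.

A learner's speed factor for a stratum is the ratio of the learner's total
duration over their interactions in that stratum to the total of the
per-(item, stratum) cohort mean durations over those same interactions: a
learner who is uniformly twice as slow as the cohort gets factor 2.0. The
classifier then flags a record when duration > factor * threshold, which
accommodates slow learners and catches brief interruptions of fast ones.
"""

from __future__ import annotations

import pandas as pd

from lapsepipe.stat_threshold import GROUP, ClassificationSet, _join_thresholds


def compute_speed_factors(
    records: pd.DataFrame,
    stats: pd.DataFrame,
    min_interactions: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (learner, stratum) speed factors.

    Numerator and denominator both sum over the learner's interactions, so
    an item encountered twice contributes its cohort mean twice. Learners
    with fewer than ``min_interactions`` usable records in a stratum get a
    neutral factor of 1. Records whose (item, stratum) has no statistics
    are excluded from both sums and reported in the second return value.

    Returns
    -------
    (factors, unmatched)
        ``factors`` has columns learner_id, stratum, factor,
        n_interactions; ``unmatched`` lists excluded records with a reason.
    """
    keyed = records.set_index(GROUP, drop=False)
    mean = stats["mean"].reindex(keyed.index)
    item_mean = pd.Series(mean.to_numpy(), index=records.index)

    missing = item_mean.isna()
    unmatched = records.loc[missing].copy()
    unmatched["reason"] = "no stats for (item, stratum)"

    sub = records.loc[~missing, ["learner_id", "stratum", "duration_s"]].copy()
    sub["item_mean"] = item_mean[~missing]
    grouped = sub.groupby(["learner_id", "stratum"]).agg(
        total_duration=("duration_s", "sum"),
        total_mean=("item_mean", "sum"),
        n_interactions=("duration_s", "count"),
    )
    grouped["factor"] = grouped["total_duration"] / grouped["total_mean"]
    grouped.loc[grouped["n_interactions"] < min_interactions, "factor"] = 1.0

    factors = grouped.reset_index()[["learner_id", "stratum", "factor", "n_interactions"]]
    return factors, unmatched.reset_index(drop=True)


def _factor_per_record(records: pd.DataFrame, factors: pd.DataFrame) -> pd.Series:
    """Map each record to its learner x stratum factor (1.0 where absent)."""
    lookup = factors.set_index(["learner_id", "stratum"])["factor"]
    keyed = records.set_index(["learner_id", "stratum"])
    s = lookup.reindex(keyed.index).fillna(1.0)
    return pd.Series(s.to_numpy(), index=records.index)


def classify_adjusted(
    records: pd.DataFrame,
    thresholds: pd.DataFrame,
    factors: pd.DataFrame,
    min_n: int = 5,
) -> ClassificationSet:
    """Flag records with duration > speed factor * group threshold."""
    thr, excluded, reasons = _join_thresholds(records, thresholds, min_n)
    keep = records.index.difference(excluded)
    s = _factor_per_record(records, factors)
    adjusted = s.loc[keep] * thr.loc[keep]
    flags = records.loc[keep, "duration_s"] > adjusted
    return ClassificationSet(
        method="speed_adjusted_mean_plus_k_sd",
        flags=flags,
        applied_threshold=adjusted,
        excluded=excluded,
        excluded_reasons=reasons,
    )


def restrict_cohort(records: pd.DataFrame, filter_spec: dict) -> pd.DataFrame:
    """Select a sub-cohort for a restricted analysis.

    ``filter_spec`` maps column names to a value or list of values; the
    special keys ``start`` / ``end`` bound ``start_time`` (inclusive,
    parseable timestamps). Downstream statistics, factors and
    classification must be recomputed on the returned subset.
    """
    mask = pd.Series(True, index=records.index)
    for key, value in filter_spec.items():
        if key == "start":
            mask &= records["start_time"] >= pd.Timestamp(value)
        elif key == "end":
            mask &= records["start_time"] <= pd.Timestamp(value)
        elif key in records.columns:
            values = value if isinstance(value, (list, tuple, set)) else [value]
            mask &= records[key].isin(values)
        else:
            raise KeyError(f"unknown filter key: {key}")
    subset = records.loc[mask]
    if len(subset) == 0:
        raise ValueError("cohort filter matched no records")
    return subset
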