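"""Mean + k*SD interruption classifier (stratified per item and stratum).

For each (item, stratum) group, the mean and sample SD of duration are
computed over all records of the group — including eventual outliers — and
an interaction is flagged as an interruption when its duration strictly
exceeds mean + k*SD (k = 2 by default). Groups smaller than ``min_n`` give
no usable threshold; their records are excluded from classification and
reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUP = ["item_id", "stratum"]


@dataclass
class ClassificationSet:
    """Per-record flags plus aggregate counts for one classifier run.

    ``flags`` is a boolean Series aligned to the classified records'
    index; ``excluded`` indexes records that could not be classified
    (no threshold, or understrength stratum).
    """

    method: str
    flags: pd.Series
    applied_threshold: pd.Series
    excluded: pd.Index = field(default_factory=lambda: pd.Index([]))
    excluded_reasons: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def n_classified(self) -> int:
        return int(len(self.flags))

    @property
    def rate(self) -> float:
        if self.n_classified == 0:
            raise ValueError("no classified records: rate undefined")
        return self.n_flagged / self.n_classified


def compute_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(item, stratum) n, mean, sample SD and median of duration.

    SD uses the n-1 denominator; a single-record group gets SD 0 rather
    than NaN so that its threshold degenerates to the mean.
    """
    if (records["duration_s"] <= 0).any():
        raise ValueError("durations must be positive")
    stats = records.groupby(GROUP)["duration_s"].agg(
        n="count", mean="mean", sd="std", median="median"
    )
    stats["sd"] = stats["sd"].fillna(0.0)
    return stats


def make_thresholds(stats: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Threshold T = mean + k*SD per (item, stratum)."""
    if len(stats) == 0:
        raise ValueError("no stratum statistics supplied")
    if k <= 0:
        raise ValueError("k must be positive")
    out = stats.copy()
    out["threshold"] = out["mean"] + k * out["sd"]
    out.attrs["k"] = k
    return out


def _join_thresholds(
    records: pd.DataFrame, thresholds: pd.DataFrame, min_n: int
) -> tuple[pd.Series, pd.Index, pd.Series]:
    """Map each record to its group's threshold; split off unclassifiable rows."""
    keyed = records.set_index(GROUP, drop=False)
    thr = thresholds["threshold"].reindex(keyed.index)
    n = thresholds["n"].reindex(keyed.index)
    thr_values = pd.Series(thr.to_numpy(), index=records.index)
    n_values = pd.Series(n.to_numpy(), index=records.index)

    reasons = pd.Series("", index=records.index, dtype=object)
    reasons[thr_values.isna()] = "no threshold for (item, stratum)"
    reasons[(~thr_values.isna()) & (n_values < min_n)] = f"stratum n < {min_n}"
    excluded = records.index[reasons != ""]
    return thr_values, excluded, reasons[reasons != ""]


def classify(
    records: pd.DataFrame,
    thresholds: pd.DataFrame,
    min_n: int = 5,
    method: str = "mean_plus_k_sd",
) -> ClassificationSet:
    """Flag records whose duration strictly exceeds their group threshold."""
    thr, excluded, reasons = _join_thresholds(records, thresholds, min_n)
    keep = records.index.difference(excluded)
    flags = records.loc[keep, "duration_s"] > thr.loc[keep]
    return ClassificationSet(
        method=method,
        flags=flags,
        applied_threshold=thr.loc[keep],
        excluded=excluded,
        excluded_reasons=reasons,
    )


def time_share(
    records: pd.DataFrame,
    classification: ClassificationSet,
) -> tuple[pd.Series, float]:
    """Interrupted share of logged time, per module attempt and on average.

    Per learner x module, share = sum of flagged durations / sum of all
    durations (classified records only); the mean across module attempts
    is returned alongside.
    """
    keep = classification.flags.index
    sub = records.loc[keep, ["learner_id", "module_id", "duration_s"]].copy()
    sub["flagged_s"] = sub["duration_s"].where(classification.flags, 0.0)
    grouped = sub.groupby(["learner_id", "module_id"])[["flagged_s", "duration_s"]].sum()
    shares = grouped["flagged_s"] / grouped["duration_s"]
    return shares, float(shares.mean())
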