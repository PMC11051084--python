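"""Modified Z-score classifier on speed-adjusted log durations.

Each duration is divided by the learner's speed factor, natural-logged
(x = ln(duration / s)), and compared against its (item, stratum) group via
the modified Z-score M = 0.6745 * (x - med(x)) / MAD, where MAD is the
median absolute deviation med(|x_i - med(x)|). Records with M strictly
above the cutoff (default 3.5) are flagged; only the high tail is flagged,
and groups with MAD = 0 flag nothing and are reported as degenerate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lapsepipe.speed_factor import _factor_per_record
from lapsepipe.stat_threshold import GROUP, ClassificationSet

MAD_COEF = 0.6745
DEFAULT_CUTOFF = 3.5


def mad(values) -> float:
    """Median absolute deviation: med(|x_i - med(x)|).

    Medians of even-length inputs are the midpoint of the two central
    order statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of empty input")
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)))


def adjusted_log_durations(records: pd.DataFrame, factors: pd.DataFrame) -> pd.Series:
    """x = ln(duration / speed factor) per record."""
    if (records["duration_s"] <= 0).any():
        raise ValueError("durations must be positive")
    s = _factor_per_record(records, factors)
    if (s <= 0).any():
        raise ValueError("speed factors must be positive")
    return np.log(records["duration_s"] / s)


def compute_robust_stats(records: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Per (item, stratum): median and MAD of x = ln(duration / s), and n."""
    x = adjusted_log_durations(records, factors)
    frame = records[GROUP].copy()
    frame["x"] = x
    out = frame.groupby(GROUP)["x"].agg(
        n="count",
        median="median",
        mad=lambda v: mad(v.to_numpy()),
    )
    return out


def classify_modified_z(
    records: pd.DataFrame,
    robust_stats: pd.DataFrame,
    factors: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    min_n: int = 5,
) -> ClassificationSet:
    """Flag records whose modified Z-score exceeds ``cutoff`` (one-sided)."""
    x = adjusted_log_durations(records, factors)
    keyed = records.set_index(GROUP)
    med = pd.Series(
        robust_stats["median"].reindex(keyed.index).to_numpy(), index=records.index
    )
    group_mad = pd.Series(
        robust_stats["mad"].reindex(keyed.index).to_numpy(), index=records.index
    )
    n = pd.Series(robust_stats["n"].reindex(keyed.index).to_numpy(), index=records.index)

    reasons = pd.Series("", index=records.index, dtype=object)
    reasons[med.isna()] = "no robust stats for (item, stratum)"
    reasons[(~med.isna()) & (n < min_n)] = f"stratum n < {min_n}"
    excluded = records.index[reasons != ""]
    keep = records.index.difference(excluded)

    degenerate = group_mad.loc[keep] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = MAD_COEF * (x.loc[keep] - med.loc[keep]) / group_mad.loc[keep]
    flags = (m > cutoff) & ~degenerate

    cls = ClassificationSet(
        method="modified_z_score",
        flags=flags,
        applied_threshold=med.loc[keep],  # group median on the log scale
        excluded=excluded,
        excluded_reasons=reasons[reasons != ""],
    )
    cls.modified_z = m.where(~degenerate)
    cls.degenerate_groups = (
        robust_stats.index[robust_stats["mad"] == 0].tolist() if len(robust_stats) else []
    )
    return cls
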