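"""Independent brute-force reimplementations used as test oracles.

Deliberately written with plain Python loops, dicts and the statistics
module so they share no code path with the package's vectorized pandas
implementations.
"""

import math
from statistics import median


def _group_key(row):
    return (row["item_id"], row["stratum"])


def stats_bruteforce(rows):
    """Per (item, stratum): n, mean, sample SD, median, by explicit loops."""
    groups = {}
    for row in rows:
        groups.setdefault(_group_key(row), []).append(row["duration_s"])
    out = {}
    for key, values in groups.items():
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        else:
            sd = 0.0
        out[key] = {"n": n, "mean": mean, "sd": sd, "median": median(values)}
    return out


def classify_bruteforce(rows, k=2.0, min_n=5):
    """Study-1 flags: True/False per record, None if unclassifiable."""
    stats = stats_bruteforce(rows)
    flags = []
    for row in rows:
        st = stats.get(_group_key(row))
        if st is None or st["n"] < min_n:
            flags.append(None)
            continue
        flags.append(row["duration_s"] > st["mean"] + k * st["sd"])
    return flags


def speed_factors_bruteforce(rows, min_interactions=3):
    """Per (learner, stratum) factor: sum durations / sum of item means."""
    stats = stats_bruteforce(rows)
    sums = {}
    for row in rows:
        st = stats.get(_group_key(row))
        if st is None:
            continue
        key = (row["learner_id"], row["stratum"])
        num, den, n = sums.get(key, (0.0, 0.0, 0))
        sums[key] = (num + row["duration_s"], den + st["mean"], n + 1)
    factors = {}
    for key, (num, den, n) in sums.items():
        factors[key] = num / den if n >= min_interactions else 1.0
    return factors


def classify_adjusted_bruteforce(rows, k=2.0, min_n=5, min_interactions=3):
    """Study-2 flags: duration > factor * (mean + k*SD)."""
    stats = stats_bruteforce(rows)
    factors = speed_factors_bruteforce(rows, min_interactions)
    flags = []
    for row in rows:
        st = stats.get(_group_key(row))
        if st is None or st["n"] < min_n:
            flags.append(None)
            continue
        s = factors.get((row["learner_id"], row["stratum"]), 1.0)
        flags.append(row["duration_s"] > s * (st["mean"] + k * st["sd"]))
    return flags


def modified_z_bruteforce(rows, cutoff=3.5, min_n=5, min_interactions=3):
    """Study-4 flags on x = ln(duration / factor), group median/MAD."""
    factors = speed_factors_bruteforce(rows, min_interactions)
    xs = {}
    for row in rows:
        s = factors.get((row["learner_id"], row["stratum"]), 1.0)
        xs.setdefault(_group_key(row), []).append(math.log(row["duration_s"] / s))
    med_mad = {}
    for key, values in xs.items():
        med = median(values)
        mad = median([abs(v - med) for v in values])
        med_mad[key] = (med, mad, len(values))
    flags = []
    for row in rows:
        s = factors.get((row["learner_id"], row["stratum"]), 1.0)
        x = math.log(row["duration_s"] / s)
        med, mad, n = med_mad[_group_key(row)]
        if n < min_n:
            flags.append(None)
        elif mad == 0:
            flags.append(False)
        else:
            flags.append(0.6745 * (x - med) / mad > cutoff)
    return flags


def sessions_bruteforce(rows, timeout_minutes=30.0):
    """Session count per (learner, module) from sorted start/end times."""
    by_module = {}
    for row in rows:
        key = (row["learner_id"], row["module_id"])
        by_module.setdefault(key, []).append(
            (row["start_time"], row["start_time"] + row["duration_s"])
        )
    counts = {}
    for key, spans in by_module.items():
        spans.sort()
        sessions = 1
        for (_, prev_end), (start, _) in zip(spans, spans[1:]):
            if start - prev_end >= timeout_minutes * 60.0:
                sessions += 1
        counts[key] = sessions
    return counts


def pearson_chi2_bruteforce(counts):
    """Textbook Pearson chi-square over the k x 2 table, cell by cell."""
    total_flagged = sum(f for f, _ in counts)
    total = sum(t for _, t in counts)
    pooled = total_flagged / total
    chi2 = 0.0
    for flagged, n in counts:
        for observed, expected in (
            (flagged, n * pooled),
            (n - flagged, n * (1 - pooled)),
        ):
            chi2 += (observed - expected) ** 2 / expected
    return chi2


def frame_to_rows(records):
    """Convert an event-log frame to plain dicts (times in epoch seconds)."""
    rows = []
    for row in records.itertuples(index=False):
        rows.append(
            {
                "learner_id": row.learner_id,
                "item_id": row.item_id,
                "module_id": row.module_id,
                "stratum": row.stratum,
                "start_time": row.start_time.timestamp(),
                "duration_s": float(row.duration_s),
            }
        )
    return rows
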