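"""Rate aggregation by month and named period, with inference.

Periods are inclusive calendar-month ranges (UTC). The default windows are
pre_covid (2019-01..2020-02), peak_covid (2020-04..2020-05) and post_peak
(2020-06..2022-12), with 2020-03 excluded as a transition month. Rates are
compared with a Pearson test of equal proportions (chi-square on the k x 2
table, df = k - 1) and pairwise Cohen's h, judged against a smallest
effect size of interest (SESOI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_PERIODS: dict[str, tuple[str, str]] = {
    "pre_covid": ("2019-01", "2020-02"),
    "peak_covid": ("2020-04", "2020-05"),
    "post_peak": ("2020-06", "2022-12"),
}

DEFAULT_EXCLUDED = ("2020-03",)

#: Seasonality-controlled windows: the same two spring months each year.
SEASONAL_PERIODS: dict[str, tuple[str, str]] = {
    "spring_2019": ("2019-04", "2019-05"),
    "spring_2020": ("2020-04", "2020-05"),
    "spring_2021": ("2021-04", "2021-05"),
    "spring_2022": ("2022-04", "2022-05"),
}

BELOW_SESOI = "below_sesoi"
AT_OR_ABOVE_SESOI = "at_or_above_sesoi"


@dataclass
class PeriodConfig:
    periods: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_PERIODS))
    excluded_months: tuple[str, ...] = DEFAULT_EXCLUDED
    sesoi: float = 0.5

    def __post_init__(self) -> None:
        if self.sesoi <= 0:
            raise ValueError("sesoi must be positive")
        spans: list[tuple[pd.Period, pd.Period, str]] = []
        excluded = {pd.Period(m, "M") for m in self.excluded_months}
        for name, (start, end) in self.periods.items():
            p0, p1 = pd.Period(start, "M"), pd.Period(end, "M")
            if p1 < p0:
                raise ValueError(f"period {name!r} ends before it starts")
            months = {p for p in pd.period_range(p0, p1, freq="M")} - excluded
            for q0, q1, other in spans:
                overlap = {p for p in pd.period_range(q0, q1, freq="M")} - excluded
                if months & overlap:
                    raise ValueError(f"periods {name!r} and {other!r} overlap")
            spans.append((p0, p1, name))


@dataclass
class PeriodReport:
    """Counts, rates, chi-square and pairwise effect sizes per period."""

    period_table: pd.DataFrame  # index: period; columns: flagged, total, rate
    chi2: float
    df: int
    p_value: float
    pairwise_h: pd.DataFrame  # columns: period_1, period_2, h, verdict
    monthly: pd.DataFrame  # index: month period; columns: flagged, total, rate
    unweighted_monthly_mean: float


def assign_period(timestamps, config: PeriodConfig | None = None) -> pd.Series:
    """Label each timestamp with its period name, 'excluded', or 'out_of_scope'.

    Month assignment uses the UTC calendar month of the timestamp.
    """
    config = config or PeriodConfig()
    ts = pd.Series(pd.to_datetime(timestamps))
    months = ts.dt.to_period("M")
    labels = pd.Series("out_of_scope", index=ts.index, dtype=object)
    for name, (start, end) in config.periods.items():
        in_span = (months >= pd.Period(start, "M")) & (months <= pd.Period(end, "M"))
        labels[in_span] = name
    excluded = months.isin([pd.Period(m, "M") for m in config.excluded_months])
    labels[excluded] = "excluded"
    return labels


def monthly_rates(
    flags: pd.Series, records: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Pooled rate per calendar month plus the unweighted mean of those rates.

    Only records covered by ``flags`` (i.e. classified) enter the counts;
    months with zero interactions are absent from the series and therefore
    from the unweighted mean.
    """
    sub = records.loc[flags.index]
    months = sub["start_time"].dt.to_period("M")
    table = pd.DataFrame({"month": months, "flagged": flags.to_numpy()})
    out = table.groupby("month")["flagged"].agg(flagged="sum", total="count")
    out["rate"] = out["flagged"] / out["total"]
    return out, float(out["rate"].mean())


def equal_proportions_test(
    counts: list[tuple[int, int]], correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test that k proportions are equal.

    ``counts`` is a list of (flagged, total) pairs. The statistic is the
    Pearson chi-square of the k x 2 table (flagged, not flagged) against
    the pooled proportion, df = k - 1. The Yates continuity correction is
    applied only when k = 2 and ``correction`` is true (matching standard
    prop.test-style behavior for larger k).
    """
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    flagged = np.array([c[0] for c in counts], dtype=float)
    total = np.array([c[1] for c in counts], dtype=float)
    if (total <= 0).any():
        raise ValueError("group totals must be positive")
    if (flagged < 0).any() or (flagged > total).any():
        raise ValueError("flagged counts must lie in [0, total]")

    k = len(counts)
    df = k - 1
    pooled = flagged.sum() / total.sum()
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate; statistic is 0", stacklevel=2)
        return 0.0, df, 1.0

    expected = np.column_stack([total * pooled, total * (1 - pooled)])
    observed = np.column_stack([flagged, total - flagged])
    dev = np.abs(observed - expected)
    if correction and k == 2:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def cohens_h(p1: float, p2: float) -> float:
    """Cohen's h for two proportions: 2*arcsin(sqrt(p1)) - 2*arcsin(sqrt(p2))."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    return float(2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2)))


def sesoi_verdict(h: float, sesoi: float) -> str:
    """Compare |h| against the smallest effect size of interest (inclusive)."""
    if sesoi <= 0:
        raise ValueError("sesoi must be positive")
    return AT_OR_ABOVE_SESOI if abs(h) >= sesoi else BELOW_SESOI


def combine_rates(within_rate: float, long_rate: float) -> float:
    """Total interruption rate: within-session + long (disjoint event classes)."""
    return within_rate + long_rate


def period_report(
    flags: pd.Series,
    records: pd.DataFrame,
    config: PeriodConfig | None = None,
) -> PeriodReport:
    """Aggregate a classification into the per-period comparison report."""
    config = config or PeriodConfig()
    sub = records.loc[flags.index]
    labels = assign_period(sub["start_time"], config)
    labels.index = sub.index

    rows = []
    counts: list[tuple[int, int]] = []
    names = [n for n in config.periods if (labels == n).any()]
    for name in names:
        mask = labels == name
        n_flagged = int(flags[mask].sum())
        n_total = int(mask.sum())
        rows.append({"period": name, "flagged": n_flagged, "total": n_total,
                     "rate": n_flagged / n_total})
        counts.append((n_flagged, n_total))
    period_table = pd.DataFrame(rows).set_index("period")

    if len(counts) >= 2:
        chi2, df, p = equal_proportions_test(counts)
    else:
        chi2, df, p = float("nan"), 0, float("nan")

    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            h = cohens_h(period_table["rate"].iloc[i], period_table["rate"].iloc[j])
            pairs.append(
                {
                    "period_1": names[i],
                    "period_2": names[j],
                    "h": h,
                    "verdict": sesoi_verdict(h, config.sesoi),
                }
            )
    pairwise = pd.DataFrame(pairs, columns=["period_1", "period_2", "h", "verdict"])

    in_scope = ~labels.isin(["excluded", "out_of_scope"])
    monthly, monthly_mean = monthly_rates(flags[in_scope], records)
    return PeriodReport(
        period_table=period_table,
        chi2=chi2,
        df=df,
        p_value=p,
        pairwise_h=pairwise,
        monthly=monthly,
        unweighted_monthly_mean=monthly_mean,
    )
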