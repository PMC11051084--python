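"""Synthetic event-log generator with ground-truth interruption labels.

Durations are log-normal per stratum, scaled by a per-learner log-normal
speed multiplier (median 1), with interruptions injected as additive
long-tailed pauses on top of genuine work time. Timestamps are laid out
sequentially within each module attempt with small organic gaps; a module
attempt may additionally receive an injected between-interaction break at
or above the session timeout, which splits it into multiple true sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lapsepipe.io_eventlog import STRATA

#: Log-scale (mu, sigma) per stratum, calibrated so initial attempts have
#: median ~28 s and subsequent attempts ~12 s, with strong right skew.
DEFAULT_BASE_PARAMS: dict[str, tuple[float, float]] = {
    "initial_attempt": (math.log(28.0), 1.0),
    "subsequent_attempt": (math.log(12.0), 0.9),
    "initial_feedback": (math.log(20.0), 0.9),
    "subsequent_feedback": (math.log(8.0), 0.8),
}

#: Distribution of attempt counts per learner x item (mastery emulation).
DEFAULT_ENCOUNTERS: dict[int, float] = {1: 0.6, 2: 0.25, 3: 0.15}


@dataclass
class GeneratorConfig:
    n_learners: int = 50
    n_modules: int = 4
    items_per_module: int = 8
    encounters: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ENCOUNTERS))
    base_duration_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_PARAMS)
    )
    speed_sigma: float = 0.4
    interruption_prob: float = 0.0
    pause_min_s: float = 300.0
    pause_scale_s: float = 300.0
    long_break_prob: float = 0.0
    timeout_minutes: float = 30.0
    calendar_start: str = "2019-01"
    calendar_end: str = "2022-12"
    organic_gap_max_s: float = 60.0
    completion_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("interruption_prob", "long_break_prob", "completion_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.speed_sigma < 0:
            raise ValueError("speed_sigma must be >= 0")
        if self.pause_scale_s <= 0 or self.pause_min_s < 0:
            raise ValueError("pause distribution parameters must be positive")
        if self.timeout_minutes <= 0:
            raise ValueError("timeout_minutes must be positive")
        if not math.isclose(sum(self.encounters.values()), 1.0, abs_tol=1e-9):
            raise ValueError("encounter probabilities must sum to 1")
        if pd.Period(self.calendar_end, "M") < pd.Period(self.calendar_start, "M"):
            raise ValueError("calendar_end precedes calendar_start")
        unknown = set(self.base_duration_params) - set(STRATA)
        if unknown:
            raise ValueError(f"unknown strata in base_duration_params: {unknown}")


@dataclass
class LabeledLog:
    """Generated records plus per-record and per-module ground truth."""

    records: pd.DataFrame
    truth: pd.DataFrame  # columns: injected (bool), pause_s (float), aligned to records
    session_truth: pd.DataFrame  # learner_id, module_id, session_truth

    def __post_init__(self) -> None:
        if len(self.truth) != len(self.records):
            raise ValueError("truth must cover every record exactly once")
        bad = (self.truth["pause_s"] > 0) != self.truth["injected"]
        if bad.any():
            raise ValueError("pause_s must be positive iff injected is set")


def _learner_rng(seed: int, learner_idx: int) -> np.random.Generator:
    # Per-learner substream: reproducible regardless of generation order.
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, learner_idx))))


def generate(config: GeneratorConfig) -> LabeledLog:
    """Generate a labeled synthetic event log. Identical config => identical log."""
    timeout_s = config.timeout_minutes * 60.0
    enc_counts = np.array(sorted(config.encounters), dtype=int)
    enc_probs = np.array([config.encounters[k] for k in sorted(config.encounters)])

    months = pd.period_range(config.calendar_start, config.calendar_end, freq="M")
    month_starts = np.array([m.to_timestamp().value // 10**9 for m in months], dtype=np.int64)
    month_lengths = np.array(
        [int((m.to_timestamp(how="end") - m.to_timestamp()).total_seconds()) for m in months],
        dtype=np.int64,
    )

    rows: list[dict] = []
    truth_rows: list[dict] = []
    session_rows: list[dict] = []

    for li in range(config.n_learners):
        rng = _learner_rng(config.seed, li)
        learner = f"L{li:05d}"
        speed = float(np.exp(rng.normal(0.0, config.speed_sigma))) if config.speed_sigma else 1.0

        for mi in range(config.n_modules):
            module = f"M{mi:03d}"
            mo = int(rng.integers(len(months)))
            t = float(month_starts[mo] + rng.integers(month_lengths[mo]))
            completed = bool(rng.random() < config.completion_prob)

            # plan interactions: per item, n attempts and n-1 feedback reviews
            plan: list[tuple[str, str, int]] = []  # (item, kind, encounter_index)
            for ii in range(config.items_per_module):
                item = f"{module}_I{ii:03d}"
                n_att = int(rng.choice(enc_counts, p=enc_probs))
                for a in range(1, n_att + 1):
                    plan.append((item, "attempt", a))
                    if a < n_att:
                        plan.append((item, "feedback_review", a))

            n_events = len(plan)
            break_positions: set[int] = set()
            if n_events >= 2 and rng.random() < config.long_break_prob:
                break_positions.add(int(rng.integers(1, n_events)))

            for pos, (item, kind, enc) in enumerate(plan):
                stratum = (
                    ("initial_" if enc == 1 else "subsequent_")
                    + ("attempt" if kind == "attempt" else "feedback")
                )
                mu, sigma = config.base_duration_params[stratum]
                base = float(np.exp(rng.normal(mu, sigma))) * speed
                injected = rng.random() < config.interruption_prob
                pause = (
                    float(config.pause_min_s + rng.exponential(config.pause_scale_s))
                    if injected
                    else 0.0
                )
                duration = base + pause

                if pos in break_positions:
                    t += timeout_s + float(rng.exponential(600.0))
                rows.append(
                    {
                        "learner_id": learner,
                        "item_id": item,
                        "module_id": module,
                        "kind": kind,
                        "encounter_index": enc,
                        "stratum": stratum,
                        "start_time": pd.Timestamp(round(t), unit="s"),
                        "duration_s": duration,
                        "completed": completed,
                    }
                )
                truth_rows.append({"injected": injected, "pause_s": pause})
                t += duration + float(rng.uniform(1.0, config.organic_gap_max_s))

            session_rows.append(
                {
                    "learner_id": learner,
                    "module_id": module,
                    "session_truth": 1 + len(break_positions),
                    "completed": completed,
                }
            )

    records = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    session_truth = pd.DataFrame(session_rows)
    return LabeledLog(records=records, truth=truth, session_truth=session_truth)


def summarize_shape(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum median, mean and SD of duration, for skew verification.

    Empty strata are omitted (a well-formed log has no empty groups to
    summarize; callers comparing against STRATA should check the index).
    """
    if len(records) == 0:
        raise ValueError("empty log")
    agg = records.groupby("stratum")["duration_s"].agg(["median", "mean", "std", "count"])
    agg = agg.rename(columns={"std": "sd", "count": "n"})
    return agg
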