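import math

import pandas as pd
import pytest

import lapsepipe as lp


def make_records(rows):
    """Build a typed event-log frame from (learner, item, module, kind,
    start_time, duration_s) tuples; strata derived."""
    df = pd.DataFrame(
        rows,
        columns=["learner_id", "item_id", "module_id", "kind", "start_time", "duration_s"],
    )
    df["start_time"] = pd.to_datetime(df["start_time"])
    df["duration_s"] = df["duration_s"].astype(float)
    records, rejects = lp.derive_strata(df)
    assert len(rejects) == 0
    return records


def attempts_at(durations, times, learner="L1", item="I1", module="M1"):
    """One learner's attempt records at explicit start times."""
    return make_records(
        [(learner, item, module, "attempt", t, d) for t, d in zip(times, durations)]
    )


@pytest.fixture(scope="session")
def default_log():
    """Mid-sized mixed-strata log with injected pauses and long breaks."""
    cfg = lp.GeneratorConfig(
        n_learners=30,
        n_modules=4,
        items_per_module=6,
        interruption_prob=0.05,
        long_break_prob=0.3,
        seed=11,
    )
    return lp.generate(cfg)


@pytest.fixture(scope="session")
def small_log():
    """Log under 1,000 records for exhaustive brute-force comparison."""
    cfg = lp.GeneratorConfig(
        n_learners=12,
        n_modules=3,
        items_per_module=5,
        interruption_prob=0.08,
        long_break_prob=0.4,
        seed=23,
    )
    log = lp.generate(cfg)
    assert len(log.records) <= 1000
    return log


RECOVERY_BASE = {"initial_attempt": (math.log(28.0), 0.5)}


def recovery_config(pi, seed=7):
    """Single-stratum config sized so detection noise stays inside the
    3-binomial-SE band: large per-item groups (thresholds stable) and many
    interactions per learner (speed factors stable)."""
    return lp.GeneratorConfig(
        n_learners=600,
        n_modules=15,
        items_per_module=20,
        encounters={1: 1.0},
        base_duration_params=dict(RECOVERY_BASE),
        interruption_prob=pi,
        pause_min_s=5000.0,
        pause_scale_s=1.0,
        speed_sigma=0.3,
        seed=seed,
    )
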