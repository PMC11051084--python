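"""Session reconstruction from inactivity gaps and long-interruption rates.

A digital session ends after ``timeout_minutes`` of inactivity; the gap
between consecutive interactions is next.start_time - (prev.start_time +
prev.duration), and a gap >= timeout starts a new session. A completed
module finished in s sessions had s - 1 long interruptions; incomplete
attempts are reported but contribute no long interruptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lapsepipe.io_eventlog import ModuleAttempt


@dataclass
class SessionPartition:
    """Session structure of one module attempt."""

    learner_id: str
    module_id: str
    session_count: int
    boundaries: list[int] = field(default_factory=list)  # positions starting a new session
    completed: bool = False

    @property
    def long_interruption_count(self) -> int:
        """Sessions minus one — defined for completed modules only."""
        if not self.completed:
            return 0
        return self.session_count - 1


def partition_sessions(
    attempt: ModuleAttempt, timeout_minutes: float = 30.0
) -> SessionPartition:
    """Split a module attempt into sessions at gaps >= the timeout.

    A gap of exactly the timeout counts as a session boundary. Raises
    ``ValueError`` on a negative gap (overlapping records); batch callers
    should use :func:`partition_all`, which quarantines such attempts.
    """
    df = attempt.interactions
    starts = df["start_time"].to_numpy()
    ends = starts + pd.to_timedelta(df["duration_s"], unit="s").to_numpy()
    gaps = (starts[1:] - ends[:-1]) / np.timedelta64(1, "s")
    if len(gaps) and gaps.min() < 0:
        raise ValueError(
            f"negative inter-interaction gap in attempt "
            f"({attempt.learner_id}, {attempt.module_id})"
        )
    timeout_s = timeout_minutes * 60.0
    boundary_positions = [int(i) + 1 for i in np.nonzero(gaps >= timeout_s)[0]]
    return SessionPartition(
        learner_id=attempt.learner_id,
        module_id=attempt.module_id,
        session_count=1 + len(boundary_positions),
        boundaries=boundary_positions,
        completed=attempt.completed,
    )


def partition_all(
    attempts: list[ModuleAttempt], timeout_minutes: float = 30.0
) -> tuple[list[SessionPartition], pd.DataFrame]:
    """Partition every attempt; quarantine those with overlapping records."""
    partitions: list[SessionPartition] = []
    quarantined: list[dict] = []
    for attempt in attempts:
        try:
            partitions.append(partition_sessions(attempt, timeout_minutes))
        except ValueError as exc:
            quarantined.append(
                {
                    "learner_id": attempt.learner_id,
                    "module_id": attempt.module_id,
                    "reason": str(exc),
                }
            )
    return partitions, pd.DataFrame(quarantined, columns=["learner_id", "module_id", "reason"])


def long_interruption_rate(
    partitions: list[SessionPartition], n_interactions: int
) -> float:
    """Sum of long interruptions over completed modules / total interactions."""
    if n_interactions <= 0:
        raise ValueError("long-interruption rate undefined with zero interactions")
    total = sum(p.long_interruption_count for p in partitions if p.completed)
    return total / n_interactions
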