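"""Event-log data model: reading, validation, stratification, module grouping.

An event log is a pandas DataFrame with one row per timed interaction:

========== ============================================================
column     meaning
========== ============================================================
learner_id opaque learner identifier (string)
item_id    opaque item identifier (string)
module_id  opaque module identifier (string)
kind       ``attempt`` or ``feedback_review``
encounter_index  1-based chronological rank within learner x item x kind
stratum    one of :data:`STRATA` (derived from kind + encounter_index)
start_time timestamp (seconds resolution, interpreted as UTC)
duration_s positive duration in seconds
completed  optional boolean: module completed by this learner
========== ============================================================

Every ingestion step partitions its input into validated rows and rejected
rows with a ``reason`` column; rows are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

KINDS = ("attempt", "feedback_review")

#: Interaction strata: statistics are always computed per item per stratum.
STRATA = (
    "initial_attempt",
    "subsequent_attempt",
    "initial_feedback",
    "subsequent_feedback",
)

_KIND_TO_STRATA = {
    "attempt": ("initial_attempt", "subsequent_attempt"),
    "feedback_review": ("initial_feedback", "subsequent_feedback"),
}

REQUIRED_COLUMNS = (
    "learner_id",
    "item_id",
    "module_id",
    "kind",
    "start_time",
    "duration_s",
)

OPTIONAL_COLUMNS = ("encounter_index", "completed")


class LogFormatError(ValueError):
    """Fatal configuration problem with an input log (e.g. missing column)."""


@dataclass
class ModuleAttempt:
    """All interactions of one learner with one module, in time order."""

    learner_id: str
    module_id: str
    interactions: pd.DataFrame
    completed: bool = False
    completion_time: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if len(self.interactions) == 0:
            raise ValueError("ModuleAttempt requires at least one interaction")
        if self.completed and self.completion_time is None:
            last = self.interactions.iloc[-1]
            self.completion_time = last["start_time"] + pd.to_timedelta(
                last["duration_s"], unit="s"
            )

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(columns=["row", "reason"])


def read_log(
    path,
    columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited event log into a validated DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row naming the required columns.
    columns
        Optional mapping from foreign header names to the canonical
        names in :data:`REQUIRED_COLUMNS` (e.g. ``{"user": "learner_id"}``).

    Returns
    -------
    (records, rejects)
        ``records`` holds every row that passed validation; ``rejects``
        holds the remaining rows with a ``reason`` column. Together they
        partition the input.

    Raises
    ------
    LogFormatError
        If a required column is absent after renaming.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if columns:
        raw = raw.rename(columns=columns)

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise LogFormatError(f"missing required column(s): {', '.join(missing)}")

    return validate_records(raw)


def validate_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split raw string-typed rows into (validated, rejects-with-reason)."""
    reasons = pd.Series("", index=raw.index, dtype=object)

    start = pd.to_datetime(raw["start_time"], errors="coerce", utc=True).dt.tz_localize(None)
    reasons[start.isna() & (reasons == "")] = "unparseable start_time"

    duration = pd.to_numeric(raw["duration_s"], errors="coerce")
    reasons[duration.isna() & (reasons == "")] = "unparseable duration"
    reasons[(duration <= 0) & (reasons == "")] = "nonpositive duration"

    bad_kind = ~raw["kind"].isin(KINDS)
    reasons[bad_kind & (reasons == "")] = "unknown interaction kind"

    if "encounter_index" in raw.columns:
        has_enc = raw["encounter_index"].astype(str).str.strip() != ""
        enc = pd.to_numeric(raw["encounter_index"], errors="coerce")
        bad_enc = has_enc & (enc.isna() | (enc < 1) | (enc != enc.round()))
        reasons[bad_enc & (reasons == "")] = "invalid encounter_index"

    ok = reasons == ""
    records = raw.loc[ok].copy()
    records["start_time"] = start[ok]
    records["duration_s"] = duration[ok].astype(float)
    if "encounter_index" in records.columns:
        enc_ok = pd.to_numeric(records["encounter_index"], errors="coerce")
        records["encounter_index"] = enc_ok.astype("Int64")
    if "completed" in records.columns:
        records["completed"] = (
            records["completed"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
        )

    rejects = raw.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def write_log(records: pd.DataFrame, path) -> None:
    """Write an event log as UTF-8 CSV (timestamps in ISO-8601, seconds)."""
    out = records.copy()
    out["start_time"] = pd.to_datetime(out["start_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def derive_strata(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign ``encounter_index`` and ``stratum`` to each record.

    Within each learner x item x kind group, records are ranked by
    ``start_time`` (ties broken by stable input order) and numbered from 1.
    The first encounter of each group is ``initial_*``; later ones are
    ``subsequent_*``. Existing ``encounter_index`` values are recomputed,
    which makes the operation idempotent.

    Rows that duplicate another row on (learner, item, kind, start_time,
    duration) are moved to the rejects channel as suspected duplicates.
    """
    dup_keys = ["learner_id", "item_id", "kind", "start_time", "duration_s"]
    dup = records.duplicated(subset=dup_keys, keep="first")
    rejects = records.loc[dup].copy()
    rejects["reason"] = "suspected duplicate"
    out = records.loc[~dup].copy()

    order = out.groupby(["learner_id", "item_id", "kind"], sort=False)["start_time"].rank(
        method="first"
    )
    out["encounter_index"] = order.astype(int)
    first = out["encounter_index"] == 1
    is_attempt = out["kind"] == "attempt"
    out["stratum"] = "subsequent_feedback"
    out.loc[first & ~is_attempt, "stratum"] = "initial_feedback"
    out.loc[~first & is_attempt, "stratum"] = "subsequent_attempt"
    out.loc[first & is_attempt, "stratum"] = "initial_attempt"
    return out.reset_index(drop=True), rejects.reset_index(drop=True)


def group_module_attempts(
    records: pd.DataFrame,
    completion_marks: pd.DataFrame | None = None,
) -> tuple[list[ModuleAttempt], pd.DataFrame]:
    """Group records into one :class:`ModuleAttempt` per learner x module.

    ``completion_marks`` is a frame with columns ``learner_id``,
    ``module_id`` and ``completed`` (optional ``completion_time``); if None,
    a ``completed`` column on the records is used, and absent that, all
    attempts are treated as incomplete. A completion mark that matches no
    interactions is rejected with a reason.
    """
    marks: dict[tuple[str, str], bool] = {}
    if completion_marks is not None:
        for row in completion_marks.itertuples(index=False):
            marks[(str(row.learner_id), str(row.module_id))] = bool(row.completed)
    elif "completed" in records.columns:
        per_mod = records.groupby(["learner_id", "module_id"])["completed"].any()
        marks = {k: bool(v) for k, v in per_mod.items()}

    attempts: list[ModuleAttempt] = []
    seen: set[tuple[str, str]] = set()
    for (learner, module), grp in records.groupby(["learner_id", "module_id"], sort=False):
        grp = grp.sort_values("start_time", kind="stable").reset_index(drop=True)
        completed = marks.get((str(learner), str(module)), False)
        attempts.append(
            ModuleAttempt(
                learner_id=str(learner),
                module_id=str(module),
                interactions=grp,
                completed=completed,
            )
        )
        seen.add((str(learner), str(module)))

    orphan_rows = [
        {"learner_id": k[0], "module_id": k[1], "reason": "completion mark without interactions"}
        for k in marks
        if k not in seen
    ]
    rejects = pd.DataFrame(orphan_rows, columns=["learner_id", "module_id", "reason"])
    return attempts, rejects
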