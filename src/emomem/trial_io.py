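"""Trial-level data model and CSV input/output.

One retrieval trial is one row: a previously encoded ("old") or new item,
the affective category of the background scene it was encoded with (old
items only), the recognition judgment (Remember/Know/Old/New depending on
the retrieval task), and the source-category attribution given whenever the
item was called old.

The interchange format is a UTF-8 comma-separated file with one header row,
lowercase snake_case column names matching :data:`TRIAL_COLUMNS`, and empty
strings for absent values.  An optional ``location_response`` column
(screen-quadrant attributions collected in some studies) is accepted and
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd


class TrialFormatError(ValueError):
    """The trial table's column layout does not match the dialect."""


class TrialValidationError(ValueError):
    """A row violates the trial-record invariants."""


GROUPS = frozenset({"control", "stress", "stress_delay"})
ENVIRONMENTS = frozenset({"EEG", "MRI", "eye_tracker"})
ENCODING_INSTRUCTIONS = frozenset({"binding", "free_viewing"})
RETRIEVAL_TASKS = frozenset({"old_new", "remember_know"})
ITEM_STATUSES = frozenset({"old", "new"})
CATEGORIES = frozenset({"pleasant", "neutral", "unpleasant"})
RECOGNITION_RESPONSES = frozenset({"remember", "know", "old", "new"})

#: Responses allowed per retrieval task.
TASK_RESPONSE_SETS = {
    "old_new": frozenset({"old", "new"}),
    "remember_know": frozenset({"remember", "know", "new"}),
}

TRIAL_COLUMNS = [
    "participant_id",
    "study",
    "group",
    "environment",
    "encoding_instruction",
    "retrieval_task",
    "n_new_items",
    "item_id",
    "item_status",
    "context_category",
    "recognition_response",
    "source_response",
]

OPTIONAL_TRIAL_COLUMNS = ["location_response"]

INDEX_COLUMNS = [
    "participant",
    "study",
    "group",
    "environment",
    "encoding_instruction",
    "retrieval_task",
    "n_new_items",
    "affective_category",
    "memory_type",
    "d_prime",
    "hu",
]


@dataclass(frozen=True)
class TrialRecord:
    """A single validated retrieval trial."""

    participant_id: str
    study: str
    group: str
    environment: str
    encoding_instruction: str
    retrieval_task: str
    n_new_items: int
    item_id: str
    item_status: str
    context_category: str | None
    recognition_response: str
    source_response: str | None

    @property
    def participant(self) -> str:
        """Globally unique participant label (study-prefixed)."""
        return f"{self.study}:{self.participant_id}"


def _enum_check(df: pd.DataFrame, column: str, allowed: frozenset) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        idx = int(df.index[bad][0])
        raise TrialValidationError(
            f"row {idx}: invalid value {df[column].iloc[df.index.get_loc(idx)]!r} "
            f"in column '{column}' (allowed: {sorted(allowed)})"
        )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the record invariants.

    Returns the table with normalized dtypes and the derived
    ``participant`` (study-prefixed, globally unique) and ``study_group``
    labels added.  Raises :class:`TrialValidationError` naming the first
    offending row otherwise.
    """
    df = trials.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing column(s): {missing}")
    unknown = [
        c
        for c in df.columns
        if c not in TRIAL_COLUMNS
        and c not in OPTIONAL_TRIAL_COLUMNS
        and c not in ("participant", "study_group", "old_judgment")
    ]
    if unknown:
        raise TrialFormatError(f"unknown column(s): {unknown}")

    for col in ("context_category", "source_response"):
        df[col] = df[col].replace("", pd.NA)
    for col in ("participant_id", "study", "item_id"):
        df[col] = df[col].astype(str)

    _enum_check(df, "group", GROUPS)
    _enum_check(df, "environment", ENVIRONMENTS)
    _enum_check(df, "encoding_instruction", ENCODING_INSTRUCTIONS)
    _enum_check(df, "retrieval_task", RETRIEVAL_TASKS)
    _enum_check(df, "item_status", ITEM_STATUSES)
    _enum_check(df, "recognition_response", RECOGNITION_RESPONSES)

    n_new = pd.to_numeric(df["n_new_items"], errors="coerce")
    if n_new.isna().any() or (n_new <= 0).any() or (n_new != n_new.astype(int)).any():
        idx = int(df.index[n_new.isna() | (n_new <= 0)][0])
        raise TrialValidationError(f"row {idx}: n_new_items must be a positive integer")
    df["n_new_items"] = n_new.astype(int)

    is_new = df["item_status"] == "new"
    bad = is_new & df["context_category"].notna()
    if bad.any():
        raise TrialValidationError(
            f"row {int(df.index[bad][0])}: new item carries a context_category"
        )
    bad = ~is_new & ~df["context_category"].isin(CATEGORIES)
    if bad.any():
        raise TrialValidationError(
            f"row {int(df.index[bad][0])}: old item lacks a valid context_category"
        )

    said_new = df["recognition_response"] == "new"
    bad = said_new & df["source_response"].notna()
    if bad.any():
        raise TrialValidationError(
            f"row {int(df.index[bad][0])}: source_response given after a 'new' judgment"
        )
    bad = df["source_response"].notna() & ~df["source_response"].isin(CATEGORIES)
    if bad.any():
        raise TrialValidationError(
            f"row {int(df.index[bad][0])}: invalid source_response"
        )

    for task, allowed in TASK_RESPONSE_SETS.items():
        bad = (df["retrieval_task"] == task) & ~df["recognition_response"].isin(allowed)
        if bad.any():
            raise TrialValidationError(
                f"row {int(df.index[bad][0])}: response "
                f"{df.loc[bad, 'recognition_response'].iloc[0]!r} not in the "
                f"{task} response set {sorted(allowed)}"
            )

    # Bare participant IDs may repeat across studies; the prefixed label is
    # the analysis-level identifier.
    df["participant"] = df["study"] + ":" + df["participant_id"]
    df["study_group"] = df["study"] + "/" + df["group"]
    return df


def read_trials(path, dialect: str = "csv") -> pd.DataFrame:
    """Read and validate a trial table.

    Parameters
    ----------
    path
        CSV file with the documented column set (one file may hold a single
        study-group or the pooled design; both layouts are plain row
        concatenations).
    dialect
        Only ``"csv"`` is defined.

    Returns
    -------
    DataFrame of validated trial records, row order preserved.
    """
    if dialect != "csv":
        raise TrialFormatError(f"unknown trial-table dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "location_response" in df.columns:
        df = df.drop(columns=["location_response"])
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the interchange dialect (empty string = absent)."""
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")


def harmonize_judgments(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the binary ``old_judgment`` flag used by the item-memory analyses.

    Remember and Know judgments are coded indistinctly as "old" calls, so
    ``old_judgment`` is true iff the recognition response is remember, know,
    or old.  The original response column is retained; the operation is
    idempotent and never changes the number of rows.
    """
    df = trials.copy()
    df["old_judgment"] = df["recognition_response"].isin(("remember", "know", "old"))
    return df


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Assemble individual :class:`TrialRecord` objects into a validated table."""
    rows = [
        {col: getattr(r, col) if getattr(r, col) is not None else pd.NA
         for col in TRIAL_COLUMNS}
        for r in records
    ]
    return validate_trials(pd.DataFrame(rows, columns=TRIAL_COLUMNS))


def write_index_table(table: pd.DataFrame, path) -> None:
    """Write a participant x category (x memory type) index table to CSV.

    Missing cells (undefined d' or Hu) are written as empty fields, never as
    zeros, so the table round-trips losslessly through
    :func:`read_index_table`.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty index table")
    missing = [c for c in INDEX_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"index table missing column(s): {missing}")
    table[INDEX_COLUMNS].to_csv(path, index=False, na_rep="")


def read_index_table(path) -> pd.DataFrame:
    """Read an index table written by :func:`write_index_table`."""
    df = pd.read_csv(path)
    missing = [c for c in INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"index table missing column(s): {missing}")
    df["participant"] = df["participant"].astype(str)
    return df[INDEX_COLUMNS]
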