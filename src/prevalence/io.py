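"""Reading participant tables.

A participant table is a CSV with header ``participant_id,p_value`` or
``participant_id,significant`` — one row per participant, ids unique.  The
column present declares whether the file carries raw within-participant
p-values (thresholded at the supplied alpha) or precomputed 0/1 flags.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import TestOutcomes

__all__ = ["read_participant_table", "outcomes_from_dataframe"]


class ParticipantTableError(ValueError):
    """Malformed participant table."""


def outcomes_from_dataframe(df: pd.DataFrame, alpha: float) -> TestOutcomes:
    cols = list(df.columns)
    if "participant_id" not in cols:
        raise ParticipantTableError(
            f"missing 'participant_id' column (found {cols})"
        )
    has_p = "p_value" in cols
    has_flag = "significant" in cols
    if has_p == has_flag:
        raise ParticipantTableError(
            "table must have exactly one of 'p_value' or 'significant' "
            f"(found {cols})"
        )
    if len(df) == 0:
        raise ParticipantTableError("table has a header but no data rows")

    ids = df["participant_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ParticipantTableError(
            f"duplicate participant_id {dup.iloc[0]!r} at row {dup.index[0] + 2}"
        )

    if has_p:
        vals = pd.to_numeric(df["p_value"], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 1)]
        if len(bad):
            raise ParticipantTableError(
                f"invalid p_value {df.loc[bad[0], 'p_value']!r} at row {bad[0] + 2}"
            )
        k = int(np.sum(vals.to_numpy() < alpha))
    else:
        vals = pd.to_numeric(df["significant"], errors="coerce")
        bad = df.index[~vals.isin([0, 1])]
        if len(bad):
            raise ParticipantTableError(
                f"invalid significant flag {df.loc[bad[0], 'significant']!r} "
                f"at row {bad[0] + 2}"
            )
        k = int(vals.sum())
    return TestOutcomes(k, int(len(df)), alpha)


def read_participant_table(path, alpha: float = 0.05) -> TestOutcomes:
    """Read a participant CSV and reduce it to (k, n, alpha) counts.

    Row numbers in error messages are 1-based file lines (header is row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParticipantTableError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParticipantTableError(f"{path}: malformed CSV: {exc}") from exc
    try:
        return outcomes_from_dataframe(df, alpha)
    except ParticipantTableError as exc:
        raise ParticipantTableError(f"{path}: {exc}") from exc
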