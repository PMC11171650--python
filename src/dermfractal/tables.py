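"""Tabular I/O shared by every pipeline stage.

All stages exchange one schema — ``id,diagnosis,fd`` plus optional derived
columns (``group,stage1,stage2``) — as CSV or XLSX, selected by file suffix.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grouping import LesionRecord

RECORD_COLUMNS = ["id", "diagnosis", "fd"]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV or XLSX table by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV or XLSX table by suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def records_to_frame(records: list[LesionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "diagnosis": r.diagnosis, "fd": r.fd} for r in records],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[LesionRecord]:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing column(s) {missing}")
    return [
        LesionRecord(str(row.id), str(row.diagnosis), float(row.fd))
        for row in df.itertuples(index=False)
    ]


def read_records(path: str | Path) -> list[LesionRecord]:
    return frame_to_records(read_table(path))


def write_records(records: list[LesionRecord], path: str | Path) -> None:
    write_table(records_to_frame(records), path)
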