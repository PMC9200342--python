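"""Reading and writing the HCA-style CSV export.

One documented dialect carries both real exports and synthetic cohorts:
comma-separated, UTF-8, header row, one row per (animal, timestamp) with
columns ``animal_id, group, week, timestamp, distance_mm, temperature_c,
separation_mm, transitions``. Timestamps are minutes since session start on
the 15-minute grid. Vendor exports with different column names are ingested
through ``column_map``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .records import CHANNELS, AnimalRecord

#: Required columns of the dialect, in on-disk order.
REQUIRED_COLUMNS = ("animal_id", "group", "week", "timestamp") + CHANNELS

NUMERIC_COLUMNS = ("week", "timestamp") + CHANNELS


class HcaFormatError(ValueError):
    """The file does not conform to the HCA CSV dialect."""


class HcaIntegrityError(ValueError):
    """The file is well-formed but internally inconsistent."""


def read_hca_csv(path: str | Path, column_map: dict[str, str] | None = None) -> list[AnimalRecord]:
    """Read an HCA-dialect CSV into a list of :class:`AnimalRecord`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional ``{on_disk_name: dialect_name}`` renaming applied before
        validation, for ingesting vendor exports with native column names.

    Rows are grouped by ``(animal_id, week)`` and sorted by timestamp within
    each record regardless of on-disk order.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise HcaFormatError(f"missing required column {col!r}")
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax()) + 2  # 1-based + header
            raise HcaFormatError(f"non-numeric value in column {col!r} at file row {row}")
        # numpy's string->float conversion is correctly rounded, which keeps
        # the write->read round trip lossless at full float64 precision
        df[col] = df[col].to_numpy(dtype=str).astype(float)
    dup = df.duplicated(subset=["animal_id", "week", "timestamp"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise HcaIntegrityError(
            "duplicate (animal, week, timestamp): "
            f"({first['animal_id']}, {int(first['week'])}, {first['timestamp']})"
        )
    records: list[AnimalRecord] = []
    for (animal_id, week), block in df.groupby(["animal_id", "week"], sort=True):
        block = block.sort_values("timestamp")
        groups = block["group"].unique()
        if len(groups) != 1:
            raise HcaIntegrityError(f"animal {animal_id!r} week {int(week)} has mixed group labels")
        records.append(
            AnimalRecord(
                animal_id=str(animal_id),
                group=str(groups[0]),
                week=int(week),
                timestamps=block["timestamp"].to_numpy(dtype=float),
                values=block[list(CHANNELS)].to_numpy(dtype=float),
            )
        )
    return records


def write_hca_csv(records: list[AnimalRecord], path: str | Path) -> int:
    """Write records to an HCA-dialect CSV; returns the number of data rows.

    Row order is deterministic: (animal_id, week, timestamp) ascending, so
    writing the same records twice yields byte-identical files.
    """
    if not records:
        raise ValueError("no records to write")
    frames = []
    for rec in sorted(records, key=lambda r: (r.animal_id, r.week)):
        frame = pd.DataFrame(rec.values, columns=list(CHANNELS))
        frame.insert(0, "timestamp", rec.timestamps)
        frame.insert(0, "week", rec.week)
        frame.insert(0, "group", rec.group)
        frame.insert(0, "animal_id", rec.animal_id)
        frames.append(frame.sort_values("timestamp"))
    table = pd.concat(frames, ignore_index=True)[list(REQUIRED_COLUMNS)]
    table["transitions"] = table["transitions"].map(_format_number)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return len(table)


def _format_number(x: float) -> float | int:
    # counts serialise as integers when exact, keeping files tidy while
    # round-tripping losslessly
    return int(x) if float(x).is_integer() else x
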