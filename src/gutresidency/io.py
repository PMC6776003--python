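"""TSV readers and writers for count tables, metadata and clone tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, validate_metadata


def read_count_matrix(path: str | Path, unit_level: str = "OTU") -> CountMatrix:
    """Read a taxon-by-sample count table.

    Tab-delimited, header row of sample ids, first column taxon ids,
    integer cells. Row and column order is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = df.index[parsed.isna()][0]
            raise ValueError(
                f"{path}: non-numeric count at row {row!r}, column {col!r}"
            )
        if (parsed % 1 != 0).any():
            row = df.index[(parsed % 1 != 0)][0]
            raise ValueError(
                f"{path}: non-integer count at row {row!r}, column {col!r}"
            )
        if (parsed < 0).any():
            row = df.index[parsed < 0][0]
            raise ValueError(
                f"{path}: negative count at row {row!r}, column {col!r}"
            )
        counts[col] = parsed.astype(np.int64)
    return CountMatrix(counts, unit_level=unit_level)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label=m.unit_level)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata table (sample_id, subject_id, date)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("sample_id", "subject_id", "date", "day") if c in meta.columns]
    meta[cols].to_csv(path, sep="\t", index=False)


CLONE_COLUMNS = ["isolate_id", "sample_id", "subject_id", "date",
                 "group_label", "clone_id", "lactose"]


def read_clone_table(path: str | Path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read an isolate/clone observation table.

    Columns: isolate_id, sample_id, subject_id, date, group_label and
    optionally clone_id (fingerprint identity, subject-scoped) and lactose
    (fermenter phenotype). Dates are normalised to per-subject day offsets;
    when sample metadata is supplied the offsets are anchored to each
    subject's first *collected* sample so they align with the schedule,
    otherwise integer dates are taken as offsets as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"isolate_id", "sample_id", "subject_id", "date", "group_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clone table missing columns: {sorted(missing)}")
    try:
        day = pd.to_numeric(df["date"]).astype(np.int64)
        numeric = True
    except (ValueError, TypeError):
        day = ((pd.to_datetime(df["date"], format="ISO8601")
                - pd.Timestamp("1970-01-01")).dt.days).astype(np.int64)
        numeric = False
    df["day"] = day
    if meta is not None:
        meta = validate_metadata(meta)
        anchor = meta.set_index("sample_id")["day"]
        bad = ~df["sample_id"].isin(anchor.index)
        if bad.any():
            raise KeyError(
                f"clone samples missing from metadata: "
                f"{sorted(df.loc[bad, 'sample_id'].unique())}"
            )
        df["day"] = df["sample_id"].map(anchor).astype(np.int64)
    elif not numeric:
        df["day"] -= df.groupby("subject_id")["day"].transform("min")
    return df


def write_clone_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CLONE_COLUMNS + ["day"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
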