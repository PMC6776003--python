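"""Core containers: sampling schedules, count matrices, presence series.

Dates are handled as integer day offsets. Calendar dates in metadata files
are parsed as ISO-8601 and converted to offsets from each subject's first
sample, so all downstream arithmetic is on plain integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("gutresidency")


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered collection days for one subject.

    ``dates`` are integer day offsets, strictly increasing, with at least
    two entries; the study period is ``[dates[0], dates[-1]]``.
    """

    subject_id: str
    dates: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.dates) < 2:
            raise ValueError(
                f"schedule for {self.subject_id!r} needs >= 2 dates, "
                f"got {len(self.dates)}"
            )
        d = np.asarray(self.dates)
        if not np.all(np.diff(d) > 0):
            raise ValueError(f"dates for {self.subject_id!r} not strictly increasing")

    @property
    def study_span(self) -> int:
        return self.dates[-1] - self.dates[0]

    @property
    def max_gap(self) -> int:
        return int(np.max(np.diff(self.dates)))


@dataclass(frozen=True)
class PresenceSeries:
    """Detection record of one taxon on one subject's schedule."""

    taxon_id: str
    schedule: SamplingSchedule
    present: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.present) != len(self.schedule.dates):
            raise ValueError(
                f"presence vector for {self.taxon_id!r} has length "
                f"{len(self.present)}, schedule has {len(self.schedule.dates)}"
            )

    @property
    def presence_dates(self) -> tuple[int, ...]:
        return tuple(d for d, p in zip(self.schedule.dates, self.present) if p)


class CountMatrix:
    """Taxon-by-sample integer count table.

    Thin wrapper over a pandas DataFrame (rows = taxa, columns = samples)
    that enforces unique ids and non-negative integer counts, and carries
    the taxonomic unit level (OTU or ASV).
    """

    def __init__(self, counts: pd.DataFrame, unit_level: str = "OTU"):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        if unit_level not in ("OTU", "ASV"):
            raise ValueError(f"unit_level must be 'OTU' or 'ASV', got {unit_level!r}")
        self._df = pd.DataFrame(
            arr.astype(np.int64), index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )
        self.unit_level = unit_level

    # -- views ---------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self._df[sample_id].to_numpy()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.unit_level == other.unit_level
            and self._df.equals(other._df)
        )

    def __repr__(self) -> str:
        nt, ns = self.shape
        return f"CountMatrix({nt} {self.unit_level}s x {ns} samples)"


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Normalise a sample-metadata table.

    Expects columns ``sample_id``, ``subject_id``, ``date`` (ISO-8601 or
    integer day offset). Returns a copy with an added ``day`` column of
    integer offsets from each subject's first sample. Rejects duplicate
    sample ids and duplicate (subject, date) pairs: the cohort design has
    one sample per subject per day, and merging would hide that.
    """
    required = {"sample_id", "subject_id", "date"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["subject_id"] = meta["subject_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    try:
        day_abs = pd.to_numeric(meta["date"])
    except (ValueError, TypeError):
        day_abs = (pd.to_datetime(meta["date"], format="ISO8601")
                   - pd.Timestamp("1970-01-01")).dt.days
    meta["_day_abs"] = day_abs.astype(np.int64)
    if meta.duplicated(subset=["subject_id", "_day_abs"]).any():
        bad = meta.loc[
            meta.duplicated(subset=["subject_id", "_day_abs"]), ["subject_id", "date"]
        ]
        raise ValueError(
            f"duplicate (subject, date) pairs in metadata:\n{bad.to_string(index=False)}"
        )
    meta["day"] = meta["_day_abs"] - meta.groupby("subject_id")["_day_abs"].transform("min")
    meta = meta.drop(columns="_day_abs")
    meta["day"] = meta["day"].astype(np.int64)
    return meta


def schedules_from_metadata(meta: pd.DataFrame) -> dict[str, SamplingSchedule]:
    """Build one :class:`SamplingSchedule` per subject from metadata."""
    meta = validate_metadata(meta)
    out = {}
    for subject, grp in meta.groupby("subject_id"):
        days = tuple(int(d) for d in sorted(grp["day"]))
        out[str(subject)] = SamplingSchedule(str(subject), days)
    return out


# ---------------------------------------------------------------------------
# operations on count matrices
# ---------------------------------------------------------------------------

def filter_low_abundance(m: CountMatrix, min_total_reads: int = 100) -> CountMatrix:
    """Drop taxa whose total read count across all samples is below a floor.

    Rare sequences (default < 100 reads over the whole dataset) are removed
    as likely artefacts; the sample set is unchanged. Idempotent.
    """
    df = m.to_frame()
    keep = df.sum(axis=1) >= min_total_reads
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_low_abundance: removed %d/%d taxa below %d total reads",
                 n_drop, len(df), min_total_reads)
    return CountMatrix(df.loc[keep], unit_level=m.unit_level)


def rarefy(m: CountMatrix, depth: int = 10_000,
           seed: int | np.random.Generator = 0) -> CountMatrix:
    """Subsample each sample to a fixed read depth without replacement.

    Each retained column is an exact multivariate-hypergeometric draw of
    ``depth`` reads from that sample's observed reads, equalising sampling
    effort across samples. Samples with fewer than ``depth`` reads are
    dropped with a logged warning rather than scaled.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = m.to_frame()
    totals = df.sum(axis=0)
    shallow = totals[totals < depth].index.tolist()
    if shallow:
        log.warning("rarefy: dropping %d samples with < %d reads: %s",
                    len(shallow), depth, shallow)
    kept = [s for s in df.columns if s not in set(shallow)]
    out = {}
    for s in kept:
        col = df[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    res = pd.DataFrame(out, index=df.index, columns=kept, dtype=np.int64)
    return CountMatrix(res, unit_level=m.unit_level)


def presence_series(m: CountMatrix, meta: pd.DataFrame, subject: str,
                    min_count: int = 1) -> dict[str, PresenceSeries]:
    """Per-taxon presence/absence on one subject's sampling schedule.

    Presence is ``count >= min_count`` (default 1) in the matrix as given;
    apply filtering/rarefaction first if presence should be scored on
    processed counts.
    """
    meta = validate_metadata(meta)
    sub = meta[meta["subject_id"] == str(subject)]
    if sub.empty:
        raise KeyError(f"subject {subject!r} not found in metadata")
    sub = sub.sort_values("day")
    samples = [s for s in sub["sample_id"] if s in set(m.sample_ids)]
    days = sub.set_index("sample_id").loc[samples, "day"].tolist()
    schedule = SamplingSchedule(str(subject), tuple(int(d) for d in days))
    df = m.to_frame()[samples]
    presence = df.to_numpy() >= min_count
    return {
        taxon: PresenceSeries(taxon, schedule, tuple(bool(x) for x in row))
        for taxon, row in zip(df.index, presence)
    }
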