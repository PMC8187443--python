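"""Text-format I/O: bedGraph tracks, BED intervals and fiber tables.

All coordinates are 0-based, half-open (BED convention). bedGraph and BED are
plain TSV; values are written with ``%g`` so canonical files round-trip
byte-identically. Nothing here merges or mutates intervals implicitly —
overlaps are allowed on read and merging is always an explicit call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BinningMismatchError, ParseError

logger = logging.getLogger("rerepkit")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
FIBER_COLUMNS = ["fiber_id", "origin_pos_kb", "left_kb", "right_kb"]


@dataclass
class Track:
    """A per-bin value track on one chromosome (bedGraph in memory)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise BinningMismatchError("starts, ends and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def bin_width(self) -> int:
        if len(self) == 0:
            return 0
        return int(self.ends[0] - self.starts[0])

    def same_binning(self, other: "Track") -> bool:
        return (
            len(self) == len(other)
            and self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )


def track_from_values(values, chrom: str = "chrSim", bin_width: int = 10_000) -> Track:
    """Build a contiguous fixed-width Track from a plain value array."""
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values), dtype=np.int64) * bin_width
    return Track(chrom, starts, starts + bin_width, values)


def _read_table(path, n_min_cols: int, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.shape[1] < n_min_cols:
        raise ParseError(f"{what} file {path} has {df.shape[1]} columns, expected >= {n_min_cols}")
    return df


def _check_intervals(start: np.ndarray, end: np.ndarray, path) -> None:
    bad = np.nonzero(end <= start)[0]
    if bad.size:
        raise ParseError(f"{path}: line {bad[0] + 1}: end <= start")


def read_bedgraph(path) -> Track:
    """Read a 4-column bedGraph; single-chromosome tracks are assumed."""
    df = _read_table(path, 4, "bedGraph")
    if df.empty:
        return Track("", np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([]))
    try:
        starts = df[1].astype(np.int64).to_numpy()
        ends = df[2].astype(np.int64).to_numpy()
        values = df[3].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric field ({exc})") from exc
    _check_intervals(starts, ends, path)
    chroms = df[0].unique()
    if len(chroms) > 1:
        raise ParseError(f"{path}: multiple chromosomes in one track ({list(chroms)[:3]}...)")
    return Track(str(chroms[0]), starts, ends, values)


def write_bedgraph(track: Track, path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:g}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6(+score); returns a DataFrame with whichever columns exist."""
    df = _read_table(path, 3, "BED")
    if df.empty:
        return pd.DataFrame(columns=BED_COLUMNS[:3])
    ncol = min(df.shape[1], 6)
    out = df.iloc[:, :ncol].copy()
    out.columns = BED_COLUMNS[:ncol]
    try:
        out["start"] = out["start"].astype(np.int64)
        out["end"] = out["end"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer coordinate ({exc})") from exc
    if "score" in out.columns:
        out["score"] = pd.to_numeric(out["score"], errors="coerce")
    _check_intervals(out["start"].to_numpy(), out["end"].to_numpy(), path)
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED; input is sorted by (chrom, start, end) on write and flagged if it was not."""
    df = intervals.copy()
    sort_cols = [c for c in ("chrom", "start", "end") if c in df.columns]
    sorted_df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        logger.warning("write_bed: input was unsorted; sorted on write (%s)", path)
    cols = [c for c in BED_COLUMNS if c in sorted_df.columns]
    with open(path, "w") as fh:
        for row in sorted_df[cols].itertuples(index=False):
            fields = []
            for c, v in zip(cols, row):
                if c == "score" and isinstance(v, float):
                    fields.append(f"{v:g}")
                else:
                    fields.append(str(v))
            fh.write("\t".join(fields) + "\n")


def read_fibers(path) -> pd.DataFrame:
    """Read a fiber table TSV with a header line (fiber_id, origin_pos_kb, left_kb, right_kb)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing fiber columns {missing}")
    return df


def write_fibers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%g")
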