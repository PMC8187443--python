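"""Condition-vs-condition replication-origin usage analysis.

Origins are scored by nascent-strand read counts per condition, library-size
normalized (counts per ``scale`` reads). Paired conditions are compared on a
log2 count-ratio axis divided into ordered fractions — from origins most
active in the y condition to origins most active in the x condition — with
peaks stratified into small (250-400 reads) and large (>400 reads) classes.
A threshold rule flags dormant origins: silent in the control condition but
strongly activated under treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidConfigError

SIZE_STATS = ("mean", "x", "y", "max")


def normalize_counts(raw, library_size: float, scale: float = 1e6) -> np.ndarray:
    """Library-size normalization: raw * scale / library_size."""
    if library_size <= 0:
        raise InvalidConfigError("library_size must be > 0")
    return np.asarray(raw, dtype=float) * (scale / library_size)


@dataclass
class OriginUsageTable:
    """Per-origin read counts across conditions, raw and normalized.

    ``intervals`` is a BED-like frame (chrom, start, end); raw counts are
    supplied per condition and normalized against each condition's library
    size (defaulting to that condition's total reads). With ``scale=None``
    (default) the scale is the mean library size across conditions, so
    normalized values stay on the raw read-count scale while being
    comparable between libraries; pass an explicit scale (e.g. 1e6 for
    counts per million) to change the units.
    """

    intervals: pd.DataFrame
    raw: dict = field(default_factory=dict)          # condition -> counts
    library_sizes: dict = field(default_factory=dict)
    scale: float | None = None

    def __post_init__(self) -> None:
        n = len(self.intervals)
        for cond, counts in self.raw.items():
            counts = np.asarray(counts)
            if len(counts) != n:
                raise InvalidConfigError(f"condition {cond!r}: {len(counts)} counts for {n} origins")
            self.raw[cond] = counts
            self.library_sizes.setdefault(cond, max(float(counts.sum()), 1.0))

    @property
    def conditions(self) -> list:
        return list(self.raw)

    def normalized(self, cond: str) -> np.ndarray:
        if cond not in self.raw:
            raise KeyError(f"unknown condition {cond!r}")
        scale = self.scale
        if scale is None:
            scale = float(np.mean(list(self.library_sizes.values())))
        return normalize_counts(self.raw[cond], self.library_sizes[cond], scale)


def pair_conditions(table: OriginUsageTable, x_cond: str, y_cond: str) -> pd.DataFrame:
    """One row per origin with normalized (x, y) counts.

    With ``table.scale=None`` the pair is normalized to the mean of the two
    conditions' library sizes (values stay on the read-count scale of the
    compared pair). Origins with no reads in a condition keep count 0 and
    are flagged in the ``missing_x`` / ``missing_y`` columns rather than
    dropped.
    """
    for cond in (x_cond, y_cond):
        if cond not in table.raw:
            raise KeyError(f"unknown condition {cond!r}")
    scale = table.scale
    if scale is None:
        scale = 0.5 * (table.library_sizes[x_cond] + table.library_sizes[y_cond])
    x = normalize_counts(table.raw[x_cond], table.library_sizes[x_cond], scale)
    y = normalize_counts(table.raw[y_cond], table.library_sizes[y_cond], scale)
    df = table.intervals.reset_index(drop=True).copy()
    df["x"], df["y"] = x, y
    df["missing_x"] = x == 0
    df["missing_y"] = y == 0
    df.attrs["x_cond"], df.attrs["y_cond"] = x_cond, y_cond
    return df


@dataclass
class FractionSummary:
    """Counts of small/large peaks across ordered log2-ratio fractions.

    Fraction 1 holds the most y-dominant origins, the last fraction the most
    x-dominant; bins are equal-width in log2-ratio space, symmetric about 0.
    """

    table: pd.DataFrame        # fraction, r_low, r_high, n_small, n_large, n_total
    r_max: float
    n_classified: int
    n_excluded: int
    thresholds: dict

    def conserved(self) -> bool:
        return int(self.table["n_total"].sum()) == self.n_classified


def _classify_sizes(x: np.ndarray, y: np.ndarray, small: tuple, large_min: float,
                    min_count: float, size_stat: str) -> tuple[np.ndarray, np.ndarray]:
    if size_stat not in SIZE_STATS:
        raise InvalidConfigError(f"size_stat must be one of {SIZE_STATS}")
    size = {"mean": (x + y) / 2.0, "x": x, "y": y,
            "max": np.maximum(x, y)}[size_stat]
    is_small = (size >= small[0]) & (size <= small[1])
    is_large = size > large_min
    return is_small, is_large


def ratio_fractions(pairs: pd.DataFrame, n_fractions: int = 10,
                    small: tuple = (250.0, 400.0), large_min: float = 400.0,
                    min_count: float = 250.0, pseudocount: float = 1.0,
                    size_stat: str = "mean") -> FractionSummary:
    """Stratify paired origins into ordered log2-ratio fractions.

    Each classified peak's statistic is r = log2((y+c)/(x+c)); peaks fall in
    equal-width half-open bins spanning [-R, R] with R = max|r| (values at +R
    go into the extreme y-dominant fraction). Peaks below ``min_count`` are
    excluded from the bar-graph classes but remain in the pairing.
    """
    if n_fractions < 2:
        raise InvalidConfigError("n_fractions must be >= 2")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    is_small, is_large = _classify_sizes(x, y, small, large_min, min_count, size_stat)
    classified = is_small | is_large
    n_exc = int((~classified).sum())
    if not classified.any():
        warnings.warn("all peaks below the minimum count; empty fraction summary")
        empty = pd.DataFrame(columns=["fraction", "r_low", "r_high",
                                      "n_small", "n_large", "n_total"])
        return FractionSummary(empty, 0.0, 0, n_exc,
                               {"small": small, "large_min": large_min, "min_count": min_count})
    r = np.log2((y[classified] + pseudocount) / (x[classified] + pseudocount))
    r_max = float(np.max(np.abs(r)))
    span = r_max if r_max > 0 else 1.0           # degenerate all-equal case: single central bin
    width = 2.0 * span / n_fractions
    asc = np.clip(np.floor((r + span) / width).astype(int), 0, n_fractions - 1)
    # present fractions from y-dominant (high r) to x-dominant (low r)
    frac_rank = n_fractions - 1 - asc
    rows = []
    for k in range(n_fractions):
        sel = frac_rank == k
        hi = span - k * width
        rows.append((k + 1, hi - width, hi,
                     int(np.sum(sel & is_small[classified])),
                     int(np.sum(sel & is_large[classified])),
                     int(np.sum(sel))))
    table = pd.DataFrame(rows, columns=["fraction", "r_low", "r_high",
                                        "n_small", "n_large", "n_total"])
    return FractionSummary(table, r_max, int(classified.sum()), n_exc,
                           {"small": small, "large_min": large_min,
                            "min_count": min_count, "pseudocount": pseudocount,
                            "size_stat": size_stat})


@dataclass
class DormantReport:
    """Origins silent in control but activated under treatment."""

    dormant: pd.DataFrame
    n_dormant: int
    n_treated_active: int
    share: float               # dormant / treated-active origins
    thresholds: tuple


def detect_dormant(pairs: pd.DataFrame, low_thresh: float = 50.0,
                   high_thresh: float = 250.0, *, control: str = "x",
                   treated: str = "y") -> DormantReport:
    """Flag dormant origins: control count < low AND treated count > high.

    The share is reported against all treated-active origins (treated count
    above ``high_thresh``), so it answers: what fraction of origins firing
    under treatment were silent in the control?
    """
    if low_thresh >= high_thresh:
        raise InvalidConfigError("low_thresh must be < high_thresh")
    c = pairs[control].to_numpy(dtype=float)
    t = pairs[treated].to_numpy(dtype=float)
    active = t > high_thresh
    dormant = (c < low_thresh) & active
    n_active = int(active.sum())
    share = float(dormant.sum() / n_active) if n_active else 0.0
    return DormantReport(pairs.loc[dormant].copy(), int(dormant.sum()),
                         n_active, share, (low_thresh, high_thresh))


def timing_stratified_pairs(pairs: pd.DataFrame, origin_groups: np.ndarray,
                            group_names: list, **fraction_kw) -> dict:
    """Per-timing-group pairing and fraction summaries (the early-to-late contrast).

    ``origin_groups`` gives one timing-group label per origin row. Returns
    {group: {"pairs": sub-frame, "fractions": FractionSummary | None,
    "mean_log2_ratio": float}} in early-to-late order.
    """
    origin_groups = np.asarray(origin_groups)
    if len(origin_groups) != len(pairs):
        raise InvalidConfigError("one group label per origin row required")
    c = fraction_kw.get("pseudocount", 1.0)
    out = {}
    for g in group_names:
        sub = pairs.loc[origin_groups == g].copy()
        if len(sub) == 0:
            out[g] = {"pairs": sub, "fractions": None, "mean_log2_ratio": np.nan}
            continue
        r = np.log2((sub["y"].to_numpy() + c) / (sub["x"].to_numpy() + c))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frac = ratio_fractions(sub, **fraction_kw)
        out[g] = {"pairs": sub, "fractions": frac,
                  "mean_log2_ratio": float(np.mean(r))}
    return out
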