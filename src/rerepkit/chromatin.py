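"""Re-replication domain segmentation and chromatin association.

Covers four analyses: (1) segmentation of a re-replicated-DNA coverage track
into domains and their stratification into peak-height quartiles; (2) the
IncRatio interval-overlap statistic (number of sample intervals touching the
reference, over the summed interval counts of both sets); (3) correlation of
re-replication abundance with a Hi-C eigen-score euchromatin proxy, with
per-abundance-group eigen distributions summarized by the 1.5*IQR box
convention; and (4) origin-anchored signal profiles (metaplots) with a
matched random-anchor control.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (InvalidConfigError, RerepKitError, TooFewDomainsError,
                     UndefinedCorrelationError)
from .io import Track

QUARTILE_LABELS = ["high", "mid-high", "mid-low", "low"]


@dataclass
class DomainSet:
    """Segmented re-replication domains with peak heights and quartile labels."""

    intervals: pd.DataFrame   # chrom, start, end, peak_height, size_bp [, quartile]

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def mean_size_bp(self) -> float:
        return float(self.intervals["size_bp"].mean()) if len(self) else 0.0


def segment_domains(track: Track, background_quantile: float = 0.5,
                    min_gap_bp: int = 0, min_size_bp: int = 0) -> DomainSet:
    """Segment bins above a background threshold into domains.

    The threshold is the given quantile of the track values; above-threshold
    runs separated by gaps shorter than ``min_gap_bp`` are merged, then
    domains shorter than ``min_size_bp`` are dropped. ``peak_height`` is the
    maximum bin value inside the (merged) domain span.
    """
    if len(track) == 0:
        raise InvalidConfigError("cannot segment an empty track")
    if not 0.0 <= background_quantile < 1.0:
        raise InvalidConfigError("background_quantile must be in [0, 1)")
    v = track.values
    thresh = np.quantile(v, background_quantile)
    above = v > thresh
    cols = ["chrom", "start", "end", "peak_height", "size_bp"]
    if not above.any():
        return DomainSet(pd.DataFrame(columns=cols))
    # run-length encode above-threshold stretches
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    run_starts, run_ends = edges[::2], edges[1::2]       # bin indices, half-open
    merged = [[run_starts[0], run_ends[0]]]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        gap_bp = int(track.starts[s] - track.ends[merged[-1][1] - 1])
        if gap_bp < min_gap_bp:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = []
    for s, e in merged:
        start, end = int(track.starts[s]), int(track.ends[e - 1])
        if end - start < min_size_bp:
            continue
        rows.append((track.chrom, start, end, float(v[s:e].max()), end - start))
    return DomainSet(pd.DataFrame(rows, columns=cols))


def quartile_stratify(domains: DomainSet) -> DomainSet:
    """Label domains by peak-height quartile: four equal-count groups, high to low.

    Ranking is by descending peak height with coordinate tie-break, so the
    labeling is deterministic and independent of input row order.
    """
    if len(domains) < 4:
        raise TooFewDomainsError(f"need >= 4 domains, got {len(domains)}")
    df = domains.intervals.copy()
    order = np.lexsort((df["start"].to_numpy(), -df["peak_height"].to_numpy()))
    labels = np.empty(len(df), dtype=object)
    for lab, chunk in zip(QUARTILE_LABELS, np.array_split(order, 4)):
        labels[chunk] = lab
    df["quartile"] = labels.astype(str)
    return DomainSet(df)


@dataclass
class OverlapReport:
    """The IncRatio overlap statistic between two interval sets."""

    n_overlaps: int
    size_sample: int
    size_reference: int
    inc_ratio: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.inc_ratio <= 1.0


def _validate_intervals(df: pd.DataFrame, what: str) -> None:
    if len(df) and (df["end"] <= df["start"]).any():
        raise RerepKitError(f"{what}: interval with end <= start")


def _merge_intervals(df: pd.DataFrame) -> dict:
    """Per-chromosome merged (start, end) arrays for overlap queries."""
    out = {}
    for chrom, grp in df.groupby("chrom"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def inc_ratio(sample: pd.DataFrame, reference: pd.DataFrame, *,
              size_mode: str = "count") -> OverlapReport:
    """IncRatio = #sample intervals overlapping the reference / (|sample| + |reference|).

    Overlap means >= 1 shared bp under half-open coordinates; a sample
    interval overlapping several reference intervals counts once. Sizes are
    interval counts (``size_mode='count'``) or covered bp (``'bp'``, where
    the numerator becomes intersection bp).
    """
    _validate_intervals(sample, "sample")
    _validate_intervals(reference, "reference")
    if size_mode not in ("count", "bp"):
        raise InvalidConfigError("size_mode must be 'count' or 'bp'")
    ref = _merge_intervals(reference) if len(reference) else {}
    if size_mode == "count":
        n_over = 0
        for chrom, grp in (sample.groupby("chrom") if len(sample) else []):
            if chrom not in ref:
                continue
            rs, re_ = ref[chrom]
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            # first merged reference interval whose end is beyond the sample start
            idx = np.searchsorted(re_, s, side="right")
            hit = (idx < len(rs)) & (rs[np.minimum(idx, len(rs) - 1)] < e)
            n_over += int(hit.sum())
        size_s, size_r = len(sample), len(reference)
    else:
        def covered(merged):
            return sum(int((e - s)) for s, e in zip(*merged))
        sam = _merge_intervals(sample) if len(sample) else {}
        size_s = sum(covered(m) for m in sam.values())
        size_r = sum(covered(m) for m in ref.values())
        n_over = 0
        for chrom, (ss, se) in sam.items():
            if chrom not in ref:
                continue
            rs, re_ = ref[chrom]
            for s, e in zip(ss, se):
                lo = np.searchsorted(re_, s, side="right")
                hi = np.searchsorted(rs, e, side="left")
                for j in range(lo, hi):
                    n_over += int(min(e, re_[j]) - max(s, rs[j]))
    denom = size_s + size_r
    return OverlapReport(int(n_over), int(size_s), int(size_r),
                         float(n_over / denom) if denom else 0.0)


@dataclass
class EigenAssociation:
    """Correlation of re-replication abundance with the eigen euchromatin proxy."""

    pearson_r: float
    pearson_p: float
    group_summary: pd.DataFrame   # per abundance group: eigen box statistics


def eigen_correlation(rerep_track: Track, eigen_track: Track,
                      n_groups: int = 4) -> EigenAssociation:
    """Pearson R across bins plus per-abundance-group eigen distributions.

    Bins are ranked by re-replication abundance into ``n_groups`` equal-count
    groups (high to low); each group's eigen scores are summarized with the
    box convention (median, quartiles, whiskers at the most extreme points
    within 1.5 * IQR of the quartiles).
    """
    if not rerep_track.same_binning(eigen_track):
        raise InvalidConfigError("tracks must share binning")
    x, y = rerep_track.values, eigen_track.values
    if len(x) < 3:
        raise InvalidConfigError("need >= 3 bins")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant track: correlation undefined")
    r, p = stats.pearsonr(x, y)
    order = np.lexsort((np.arange(len(x)), -x))
    rows = []
    for lab, chunk in zip(QUARTILE_LABELS[:n_groups], np.array_split(order, n_groups)):
        ey = y[chunk]
        q1, med, q3 = np.percentile(ey, [25, 50, 75])
        iqr = q3 - q1
        in_lo = ey[ey >= q1 - 1.5 * iqr]
        in_hi = ey[ey <= q3 + 1.5 * iqr]
        rows.append((lab, len(ey), med, q1, q3,
                     float(in_lo.min()), float(in_hi.max())))
    summary = pd.DataFrame(rows, columns=["group", "n", "median", "q25", "q75",
                                          "whisker_low", "whisker_high"])
    return EigenAssociation(float(r), float(p), summary)


@dataclass
class AnchorProfile:
    """Mean signal around anchors (metaplot) with optional stratification."""

    offsets_bp: np.ndarray
    mean_profile: np.ndarray
    anchor_scores: np.ndarray                 # per-anchor mean over +/- flank
    profile_se: np.ndarray | None = None      # per-offset standard error
    group_profiles: dict = field(default_factory=dict)
    group_scores: dict = field(default_factory=dict)
    random_profile: np.ndarray | None = None
    random_scores: np.ndarray | None = None
    random_se: np.ndarray | None = None
    n_clipped: int = 0


def _window_matrix(values: np.ndarray, bins: np.ndarray, flank_bins: int) -> np.ndarray:
    n = len(values)
    offs = np.arange(-flank_bins, flank_bins + 1)
    idx = bins[:, None] + offs[None, :]
    mat = np.full(idx.shape, np.nan)
    ok = (idx >= 0) & (idx < n)
    mat[ok] = values[np.clip(idx, 0, n - 1)][ok]
    return mat


def anchor_profile(signal: Track, anchors_bp: np.ndarray, flank_bp: int,
                   groups: np.ndarray | None = None,
                   group_names: list | None = None, *,
                   n_random: int | None = None, seed: int = 0,
                   exclude_bp: int | None = None) -> AnchorProfile:
    """Mean signal at each offset across anchors, centered on the anchors.

    ``groups`` (one label per anchor) adds per-timing-group profiles. With
    ``n_random`` a matched random-anchor control is drawn uniformly over the
    track, excluding positions within ``exclude_bp`` (default: the flank) of
    a real anchor; widen the exclusion when the anchor-associated signal
    extends beyond the anchors themselves.
    """
    bw = signal.bin_width
    if bw <= 0 or flank_bp < bw:
        raise InvalidConfigError("flank must be at least one bin")
    flank_bins = int(flank_bp // bw)
    anchors_bp = np.asarray(anchors_bp, dtype=np.int64)
    bins = anchors_bp // bw
    inside = (bins >= 0) & (bins < len(signal))
    n_clipped = int((~inside).sum())
    bins = bins[inside]
    if len(bins) == 0:
        raise InvalidConfigError("no anchors inside the track")
    mat = _window_matrix(signal.values, bins, flank_bins)
    offsets = np.arange(-flank_bins, flank_bins + 1) * bw
    n_eff = np.sum(~np.isnan(mat), axis=0)
    prof = AnchorProfile(offsets, np.nanmean(mat, axis=0),
                         np.nanmean(mat, axis=1),
                         profile_se=np.nanstd(mat, axis=0) / np.sqrt(np.maximum(n_eff, 1)),
                         n_clipped=n_clipped)
    if groups is not None:
        groups = np.asarray(groups)[inside]
        names = group_names if group_names is not None else list(pd.unique(groups))
        for g in names:
            sel = groups == g
            if sel.any():
                prof.group_profiles[g] = np.nanmean(mat[sel], axis=0)
                prof.group_scores[g] = float(np.nanmean(mat[sel]))
    if n_random:
        rng = np.random.default_rng(seed)
        excl_bins = flank_bins if exclude_bp is None else int(exclude_bp // bw)
        excluded = np.zeros(len(signal), dtype=bool)
        for b in bins:
            excluded[max(0, b - excl_bins):b + excl_bins + 1] = True
        allowed = np.flatnonzero(~excluded)
        if len(allowed) == 0:
            raise InvalidConfigError("no room for random anchors outside real windows")
        rbins = rng.choice(allowed, size=n_random, replace=True)
        rmat = _window_matrix(signal.values, rbins, flank_bins)
        n_eff = np.sum(~np.isnan(rmat), axis=0)
        prof.random_profile = np.nanmean(rmat, axis=0)
        prof.random_scores = np.nanmean(rmat, axis=1)
        prof.random_se = np.nanstd(rmat, axis=0) / np.sqrt(np.maximum(n_eff, 1))
    return prof
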