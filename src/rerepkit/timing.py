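"""Replication-timing inference from binned copy-number coverage.

In an asynchronous population, early-replicating regions are duplicated in
more cells and therefore sequenced at higher coverage than late-replicating
ones; the log2 ratio of S-phase (or re-replicating) coverage over G1 coverage
orders the genome from early to late. Two stratifications are supported:

* ``six_range`` — boundaries at fixed percentiles of the total ratio *range*
  (not quantiles): the top 10% of the range is Very Early, then Early
  (10-30%), Mid-Early (30-50%), Mid-Late (50-70%), Late (70-90%) and
  Very Late (90-100%). Group sizes need not be equal.
* ``four_equal`` — bins ranked by ratio and split into four equal-count
  groups (Early, Mid-Early, Mid-Late, Late), ties broken by coordinate.

Amplification scores contrast two ratio tracks (re-replicating minus
control) per bin or per element, summarized within timing groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .errors import BinningMismatchError, DegenerateRangeError, InvalidConfigError
from .io import Track

SIX_GROUPS = ["Very Early", "Early", "Mid-Early", "Mid-Late", "Late", "Very Late"]
FOUR_GROUPS = ["Early", "Mid-Early", "Mid-Late", "Late"]
# Range-percentile widths measured downward from the top of the ratio range;
# the high-coverage (high-ratio) end of the range is the early end.
SIX_RANGE_PERCENTILES = (0.10, 0.30, 0.50, 0.70, 0.90)


@dataclass
class RatioTrack:
    """Per-bin log2 coverage ratio with the pseudocount that produced it."""

    track: Track
    pseudocount: float
    median_centered: bool = False
    smooth_window: float = 0.0
    smooth_kind: str = "mean"

    @property
    def values(self) -> np.ndarray:
        return self.track.values

    def __len__(self) -> int:
        return len(self.track)


@dataclass
class TimingGroups:
    """Per-bin timing-group labels from an ordered early-to-late label set."""

    labels: np.ndarray            # per-bin label strings
    scheme: str                   # 'six_range' or 'four_equal'
    group_names: list             # ordered earliest -> latest
    boundaries: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.labels)

    def ordinal(self) -> np.ndarray:
        """0 = earliest group, increasing toward late."""
        index = {g: i for i, g in enumerate(self.group_names)}
        return np.array([index[g] for g in self.labels])


def log2_ratio(s_cov: Track, g1_cov: Track, pseudocount: float = 1.0,
               *, median_center: bool = False, smooth_window: float = 0.0,
               smooth_kind: str = "mean") -> RatioTrack:
    """log2((s + c) / (g1 + c)) per bin.

    Smoothing is off unless ``smooth_window`` (in bins) is set: ``mean``
    applies a running-mean filter of that width, ``gaussian`` a Gaussian
    kernel with that sigma. ``median_center`` subtracts the (post-smoothing)
    median. Both choices are recorded on the returned track.
    """
    if pseudocount <= 0:
        raise InvalidConfigError("pseudocount must be > 0")
    if not s_cov.same_binning(g1_cov):
        raise BinningMismatchError("S and G1 tracks must share binning")
    r = np.log2((s_cov.values + pseudocount) / (g1_cov.values + pseudocount))
    if smooth_window:
        if smooth_kind == "mean":
            r = uniform_filter1d(r, int(smooth_window), mode="nearest")
        elif smooth_kind == "gaussian":
            r = gaussian_filter1d(r, smooth_window, mode="nearest")
        else:
            raise InvalidConfigError("smooth_kind must be 'mean' or 'gaussian'")
    if median_center:
        r = r - np.median(r)
    out = Track(s_cov.chrom, s_cov.starts, s_cov.ends, r)
    return RatioTrack(out, pseudocount, median_center, smooth_window, smooth_kind)


def stratify_by_range_percentile(ratio: RatioTrack | np.ndarray,
                                 scheme: str = "six_range") -> TimingGroups:
    """Assign every bin to a timing group under the chosen scheme."""
    r = ratio.values if isinstance(ratio, RatioTrack) else np.asarray(ratio, dtype=float)
    n = len(r)
    if n == 0:
        raise InvalidConfigError("cannot stratify an empty track")
    if scheme == "six_range":
        lo, hi = r.min(), r.max()
        if hi == lo:
            raise DegenerateRangeError("constant ratio: range-percentile groups undefined")
        span = hi - lo
        # ascending boundaries; the top of the range maps to Very Early
        bounds = lo + span * (1.0 - np.array(SIX_RANGE_PERCENTILES))[::-1]
        idx = np.digitize(r, bounds, right=False)   # 0 = lowest ratio = Very Late
        names_ascending = SIX_GROUPS[::-1]
        labels = np.array([names_ascending[i] for i in idx])
        return TimingGroups(labels, scheme, list(SIX_GROUPS), bounds)
    if scheme == "four_equal":
        # rank by ratio descending (highest coverage = earliest), ties by coordinate
        order = np.lexsort((np.arange(n), -r))
        labels = np.empty(n, dtype=object)
        for g, chunk in zip(FOUR_GROUPS, np.array_split(order, 4)):
            labels[chunk] = g
        return TimingGroups(labels.astype(str), scheme, list(FOUR_GROUPS))
    raise InvalidConfigError(f"unknown scheme {scheme!r}")


@dataclass
class AmplificationTable:
    """Per-element amplification scores with per-timing-group summaries."""

    scores: pd.DataFrame       # columns: element, group, score
    summary: pd.DataFrame      # per group: n, median, q25, q75, p5, p95

    def group_medians(self) -> pd.Series:
        return self.summary.set_index("group")["median"]


def amplification_scores(rerep: RatioTrack, control: RatioTrack,
                         groups: TimingGroups,
                         element_bins: np.ndarray | None = None) -> AmplificationTable:
    """Amplification score = re-replication log2 ratio minus control log2 ratio.

    ``element_bins`` restricts scoring to specific elements (e.g. origin
    bins); by default every bin is an element. Summaries use the box
    convention: median, quartiles, and 5th/95th percentiles.
    """
    if not rerep.track.same_binning(control.track):
        raise BinningMismatchError("ratio tracks must share binning")
    if len(groups) != len(rerep):
        raise BinningMismatchError("timing groups must match track binning")
    bins = np.arange(len(rerep)) if element_bins is None else np.asarray(element_bins)
    if bins.size and (bins.min() < 0 or bins.max() >= len(rerep)):
        raise InvalidConfigError("element bin outside track")
    score = rerep.values[bins] - control.values[bins]
    df = pd.DataFrame({"element": bins, "group": groups.labels[bins], "score": score})
    rows = []
    for g in groups.group_names:
        s = df.loc[df["group"] == g, "score"]
        if len(s) == 0:
            rows.append((g, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
        else:
            rows.append((g, len(s), s.median(), s.quantile(0.25), s.quantile(0.75),
                         s.quantile(0.05), s.quantile(0.95)))
    summary = pd.DataFrame(rows, columns=["group", "n", "median", "q25", "q75", "p5", "p95"])
    return AmplificationTable(df, summary)


def trend_test(scores: np.ndarray, group_ordinals: np.ndarray,
               n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutation trend test across ordered groups.

    Statistic: Spearman correlation between group ordinal and score
    (a Jonckheere-style ordered-alternative test). Returns (statistic,
    two-sided permutation p-value).
    """
    scores = np.asarray(scores, dtype=float)
    g = np.asarray(group_ordinals, dtype=float)
    if len(scores) != len(g) or len(scores) < 3:
        raise InvalidConfigError("need >= 3 paired observations")
    obs = stats.spearmanr(g, scores).statistic
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = stats.spearmanr(g, rng.permutation(scores)).statistic
    p = (1 + np.sum(np.abs(perm) >= abs(obs))) / (n_perm + 1)
    return float(obs), float(p)


def assign_bins_to_positions(positions_bp: np.ndarray, bin_width: int,
                             n_bins: int) -> tuple[np.ndarray, int]:
    """Map genomic positions to bin indices; out-of-genome positions are dropped.

    Returns (bin indices of retained positions, number dropped).
    """
    pos = np.asarray(positions_bp, dtype=np.int64)
    idx = pos // bin_width
    keep = (idx >= 0) & (idx < n_bins)
    return idx[keep], int((~keep).sum())
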