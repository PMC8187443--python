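"""DNA-combing analytics: fork rates, inter-origin distances and fork asymmetry.

Fibers carry an origin with two sister forks labeled over sequential analog
pulses; the labeled track lengths give fork progression rates, and unequal
sister-fork lengths flag stalling. A bidirectional structure is called
asymmetric when the relative length difference |L - R| / max(L, R) exceeds a
threshold (default 30%, strict inequality). Group comparisons use the
Mann-Whitney rank-sum test for continuous measures and the 2x2 chi-square
for asymmetric-fork prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (EmptyInputError, InvalidConfigError, InvalidRecordError,
                     InvalidTableError)
from .simcore import FiberSet


def fork_rate(length_kb, label_minutes: float):
    """Fork progression rate in kb/min."""
    if label_minutes <= 0:
        raise InvalidConfigError("label_minutes must be > 0")
    length = np.asarray(length_kb, dtype=float)
    if np.any(length < 0):
        raise InvalidRecordError("negative fork length")
    out = length / label_minutes
    return float(out) if np.isscalar(length_kb) else out


def fork_rates(fibers: FiberSet) -> np.ndarray:
    """Per-fork rates: total labeled length of both sides over total label time.

    One-sided structures (one measurable label segment) contribute their
    single side; forks with neither side measured are skipped.
    """
    df = fibers.records
    left = df["left_kb"].to_numpy(dtype=float)
    right = df["right_kb"].to_numpy(dtype=float)
    both = ~np.isnan(left) & ~np.isnan(right)
    one = np.isnan(left) ^ np.isnan(right)
    rates = []
    # both sides: mean of the two per-fork rates == total length / (2 * label time)
    rates.append((left[both] + right[both]) / (2 * fibers.label_minutes))
    single = np.where(np.isnan(left[one]), right[one], left[one])
    rates.append(single / fibers.label_minutes)
    return np.concatenate(rates)


def inter_origin_distances(fibers: FiberSet) -> np.ndarray:
    """Successive center-to-center origin distances (kb) on multi-origin fibers."""
    out = []
    for _, grp in fibers.records.groupby("fiber_id", sort=False):
        pos = np.sort(grp["origin_pos_kb"].to_numpy(dtype=float))
        if len(pos) >= 2:
            out.append(np.diff(pos))
    return np.concatenate(out) if out else np.array([])


def classify_fork_symmetry(left_kb: float, right_kb: float,
                           threshold: float = 0.30, *,
                           denominator: str = "max") -> str:
    """'asymmetric' iff |L - R| / max(L, R) > threshold (strict).

    ``denominator='mean'`` divides by the mean of the two sides instead.
    """
    if left_kb < 0 or right_kb < 0:
        raise InvalidRecordError("fork lengths must be >= 0")
    if left_kb == 0 and right_kb == 0:
        raise InvalidRecordError("both fork lengths are zero")
    if denominator == "max":
        denom = max(left_kb, right_kb)
    elif denominator == "mean":
        denom = (left_kb + right_kb) / 2.0
    else:
        raise InvalidConfigError("denominator must be 'max' or 'mean'")
    return "asymmetric" if abs(left_kb - right_kb) / denom > threshold else "symmetric"


@dataclass
class AsymmetrySummary:
    """Prevalence of asymmetric sister forks among bidirectional structures."""

    n_forks: int
    n_asymmetric: int
    percentage: float
    threshold: float
    n_excluded: int = 0          # forks missing one side

    def __post_init__(self) -> None:
        assert 0.0 <= self.percentage <= 100.0
        assert self.n_asymmetric <= self.n_forks


def asymmetry_summary(fibers: FiberSet, threshold: float = 0.30, *,
                      denominator: str = "max") -> AsymmetrySummary:
    """Classify every bidirectional fork; one-sided structures are excluded and counted."""
    df = fibers.records
    left = df["left_kb"].to_numpy(dtype=float)
    right = df["right_kb"].to_numpy(dtype=float)
    valid = ~np.isnan(left) & ~np.isnan(right)
    n_excluded = int((~valid).sum())
    left, right = left[valid], right[valid]
    if len(left) == 0:
        raise EmptyInputError("no bidirectional forks to classify")
    if np.any(left < 0) or np.any(right < 0) or np.any((left == 0) & (right == 0)):
        raise InvalidRecordError("invalid fork record (negative or doubly-zero lengths)")
    if denominator == "max":
        denom = np.maximum(left, right)
    elif denominator == "mean":
        denom = (left + right) / 2.0
    else:
        raise InvalidConfigError("denominator must be 'max' or 'mean'")
    asym = np.abs(left - right) / denom > threshold
    n = len(left)
    return AsymmetrySummary(n, int(asym.sum()), 100.0 * asym.mean(), threshold, n_excluded)


def rank_sum_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_a, p).

    Exact enumeration when both samples are small (min size <= 8) and the
    pooled values have no ties; the tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidConfigError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_by_two_chisq(a: int, b: int, c: int, d: int, *,
                     continuity: bool = False) -> tuple[float, float]:
    """Chi-square test on the 2x2 table [[a, b], [c, d]], df = 1.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the optional Yates
    correction subtracts N/2 from |ad - bc| (floored at 0).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise InvalidTableError("counts must be >= 0")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise InvalidTableError("2x2 table has a zero margin")
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff ** 2 / np.prod([float(m) for m in margins])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
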