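# Methods

`rerep-kit` analyzes DNA re-replication — re-initiation of DNA synthesis on
already-replicated chromatin within one cell cycle — with a seeded
stochastic simulator supplying every input the analysis stages consume.
This note documents the model, its assumptions, the parameters that matter,
and what the synthetic data do and do not establish about real data.

## The simulated genome

A genome is one chromosome of `n_bins` fixed-width bins (default 1000 ×
10 kb = 10 Mb). Two per-bin fields are generated:

* **Replication timing** `t ∈ [0, 1]` (0 = earliest): Gaussian noise
  low-pass filtered with a Gaussian kernel (`smooth_bins`, default σ = 50
  bins = 500 kb) and min–max rescaled. This produces contiguous,
  megabase-scale early/late timing domains, the feature of real timing
  profiles the analyses depend on; it does not model centromeres,
  chromosome arms or isochore structure.
* **Euchromatin score** (a Hi-C eigen-score proxy; positive = euchromatin):
  the negated standardized timing plus Gaussian noise whose amplitude
  shrinks as the `coupling` parameter rises from 0 (independent tracks) to
  1 (euchromatin is a deterministic function of timing). Early-replicating
  chromatin is euchromatic by construction, which is the association the
  chromatin analyses are designed to detect.

**Origins** are placed by sampling bins with intensity
`exp(κ·(1 − t))`: `κ = 0` gives spatially uniform licensing, `κ = 2`
(default) concentrates licensed origins — and their licensing weight, a
CDT1/pre-RC density proxy — in early-replicating chromatin. Weights carry
mild lognormal origin-to-origin variation (σ = 0.2). A configurable
fraction of origins (default 15%) is flagged *dormant*: licensed but firing
with probability ≤ 0.01 outside replication stress. The default licensed
density is 30/Mb (one per ~33 kb); with the default per-cycle firing
probability of 0.6 this gives fired-origin spacing of ~55 kb, reflecting
the well-known excess of licensed over fired origins.

## Population kinetics

**Normal S phase.** Each competent origin fires per cell with probability
`fire_prob_normal` (default 0.6) at a time proportional to its local timing
value plus truncated-Gaussian jitter (σ = 0.05 of S phase). Forks extend
bidirectionally at `fork_speed_kb_per_min` (default 1.5); a bin's
replication time is the earliest arrival over fired origins, so unfired
regions replicate passively. Cells are harvested at a point uniform in
[0, 1] of their own S-phase progress; the harvest points are implemented as
a stratified (quasi-Monte-Carlo) uniform grid over the population, which
removes sampling noise in the progress distribution without changing the
uniform-harvest assumption. Per-cell copy number is therefore 1 or 2 —
never more — and the population mean copy decreases from early to late
bins, which is what the timing inference reads out.

**Re-replication.** The first round runs to completion (re-initiation is
only permitted after the normal round finishes, consistent with the
observation that re-initiation does not immediately follow initial
replication). The *same* origin pool then re-fires with probability
`relicense_prob · w · exp(−β·t)` per origin: `β` (default 2) is the sole
knob for the early-timing preference of re-initiation, with the licensing
weight `w` adding the CDT1 skew when origins were placed with `κ > 0`.
Each re-initiation extends forks over a window of
`rerep_minutes × fork speed` scaled by a per-event factor drawn uniformly
from [0.5, 1], independent of timing. The population is harvested after
every re-fired origin has completed its window. This choice matters: if
re-round fork extents depended on re-firing *time*, even `β = 0` would
produce an early-coverage bias through the conserved firing order, and the
β = 0 control condition would show a spurious timing trend. With
timing-independent extents, β alone controls the early bias, and β = 0
re-replication is uniform along the genome. Copy number in covered bins
rises above 2 (one extra copy per overlapping re-initiation).

**Replication stress.** Normal kinetics with dormant origins promoted to a
firing probability of 0.7 and forks slowed 2-fold — the aphidicolin-like
condition used for the dormant-origin contrast.

**Probabilities are per label window / per round, not per minute.**

## BrdU substitution and the density gradient

Strand substitution is tracked per bin on a representative (newest) duplex:
the first labeled replication marks one strand (heavy-light, HL), any
subsequent replication of that locus marks both (heavy-heavy, HH); an
unreplicated locus is light-light (LL). This deliberate simplification —
one fragment state per bin per cell rather than a census of all sister
duplexes — makes two properties exact by construction: the HH fragment
fraction equals the re-replicated template fraction, and a label spanning
two full doublings yields pure HH. (A full per-duplex census would instead
give an HH share of f/(1+f) after one re-round, because each re-replication
also regenerates an HL sibling; the representative-duplex convention is
what the HH/HL gradient readout of re-replicated DNA corresponds to.)

The CsCl gradient draws each fragment's buoyant density from
Normal(ρ_class, sd) with ρ_LL < ρ_HL < ρ_HH (defaults 1.70, 1.755,
1.81 g/cm³, sd 0.005) and histograms fragments into equal-width fractions
spanning the class densities ± 4 sd; draws outside are clipped into the
end fractions so mass is conserved. Fraction edges are shifted by half a
fraction width when a class density would fall exactly on an edge, so a
sharp band occupies one fraction. A fraction belongs to the *window* of
the nearest class density; window mass over total mass is the reported
class share.

## Replication timing inference

Timing is inferred as `log2((S + c)/(G1 + c))` per bin (pseudocount
`c = 1` to admit zero-coverage bins; no smoothing unless requested — an
optional running-mean or Gaussian filter is available and is used with
σ = 20 bins when stratifying noisy coverage). Two stratifications:

* **six_range**: boundaries at fixed percentiles of the total ratio
  *range* (not quantiles) — the top 10% of the range is Very Early, then
  Early (10–30%), Mid-Early (30–50%), Mid-Late (50–70%), Late (70–90%),
  Very Late (90–100%). The high-ratio end is the early end because early
  regions are present at higher copy in asynchronous cells. Intervals are
  half-open with the top bin closed; group sizes need not be equal.
* **four_equal**: bins ranked by ratio and split into four equal-count
  groups, ties broken by genomic coordinate for determinism.

Median-centering of the ratio is available but off by default.

**Amplification scores** are the difference of log2 ratios,
re-replicating minus control, per bin or per origin, summarized per timing
group by median, quartiles and 5th/95th percentiles. The control is a
*completed-S* (G2-like) population over G1 — not the asynchronous mid-S
population — because the asynchronous control carries its own early/late
coverage slope, which would cancel (and at late bins reverse) the
re-replication signal; timing *groups* are still inferred from the
asynchronous ratio, which is where the timing information lives. A
permutation trend test (Spearman statistic of score against group ordinal,
two-sided) checks for ordered trends; when scores are spatially
autocorrelated the test is applied to elements spaced beyond the
correlation length (every 25th bin in the shipped analyses), since bin-wise
permutation would otherwise overstate significance.

**Known limitation.** Agreement between inferred four-group timing and the
simulator's *latent* firing-time field is structurally capped at roughly
85–94% of bins across genome realizations: passive replication between
origins genuinely reorders bins relative to the latent field, and the
firing-pattern noise of a 500-cell population is spatially correlated, so
neither deeper sequencing nor smoothing removes it. The realized expected
replication time is exposed as `PopulationResult.mean_rep_frac`; it matches
the copy-number ranks almost perfectly but contains sub-smoothing-scale
structure that 50-reads-per-bin coverage cannot resolve. The shipped study
genome sits near the top of that band (91–94% agreement across coverage
draws). Passing this recovery check therefore shows the inference machinery
is sound at realistic noise, not that bin-level timing calls on real data
reach that accuracy.

## Origin-usage comparison

Per-origin nascent-strand (NS-seq) read counts are Poisson with mean
`depth × firing frequency` in the relevant round; the HH condition counts
only re-round initiations. Library-size normalization follows
`raw × scale / library_size`; when two conditions are paired, the default
scale is the mean of the two library sizes, keeping normalized values on
the read-count scale so the fixed thresholds below apply directly (an
explicit `scale = 10^6` gives counts per million).

Paired origins are stratified on `r = log2((y + 1)/(x + 1))` into 10
equal-width half-open fractions spanning [−R, R] with `R = max |r|`,
presented from y-dominant to x-dominant (equal-count deciles are available
behind a flag; the equal-width convention is the package's choice where
the binning was not fully specified). Peaks are classed *small* when the
mean of the two conditions' counts lies in [250, 400], *large* above 400,
and excluded below 250 (the condition used for sizing is configurable).
Dormant origins are called by threshold: control-normalized count < 50 and
treated-normalized count > 250, with the dormant share reported against
treated-active origins (> 250).

## Chromatin association

* **Domain segmentation**: bins above a background quantile (default 0.9
  of the track) are run-length encoded; runs separated by gaps below
  `min_gap_bp` (10 kb) merge; domains shorter than `min_size_bp` (20 kb)
  drop. Peak height is the maximum bin value in the domain. Quartile
  stratification ranks domains by peak height (coordinate tie-break) into
  four equal-count groups, high → low.
* **IncRatio** = (# sample intervals overlapping ≥ 1 reference interval) /
  (# sample intervals + # reference intervals), half-open coordinates,
  each sample interval counted once. Sizes are interval counts (GIGGLE
  convention); a bp mode is available. Because counting is per sample
  interval, the attainable maximum is |sample|/(|sample|+|reference|).
* **Eigen correlation**: Pearson R between a coverage track and the eigen
  proxy across bins; per-abundance-group eigen distributions use the box
  convention with whiskers at the most extreme points within 1.5 × IQR of
  the quartiles.
* **Anchor profiles**: mean signal per offset over ± flank around anchor
  positions, with per-offset standard errors, optional per-timing-group
  profiles, and a seeded random-anchor control matched in count. Random
  centers exclude positions within `exclude_bp` (default: the flank) of a
  real anchor; widen the exclusion when the anchored signal has support
  beyond the anchor itself (the shipped analyses use 100 kb for ~15 kb-wide
  licensing peaks). Profiles at track edges are NaN-padded and averaged
  over available anchors.

## Statistics

The Mann–Whitney rank-sum test uses exact enumeration when both samples
are small (min n ≤ 8) and tie-free, otherwise the tie-corrected normal
approximation; two-sided throughout. The 2×2 chi-square uses the closed
form `N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))` with df = 1, no continuity
correction by default (Yates available). Fork asymmetry uses
`|L − R| / max(L, R) > 0.30` (strict inequality; the max denominator is the
conservative symmetric choice, mean available); one-sided fork structures
are excluded from asymmetry but included in rate statistics, where a
bidirectional fork's rate is total labeled length over total label time.

## Fibers

Each simulated fiber carries 1 + Poisson(0.7) origins spaced exponentially
(mean 100 kb). Each fork side runs the full double-label window
(20 + 20 min) unless it stalls — probability `stall_prob` per side per
window — at a uniform time, truncating the labeled track. Optical
measurement noise is multiplicative lognormal with 5% CV by default, so a
control condition shows a small nonzero asymmetric-fork percentage, as real
combing data do. An independent 10⁶-draw Monte-Carlo of the same stall
model (unit speed/time, no optical noise) serves as the oracle for the
asymmetric-fork prevalence.

## Problem sizes and reproducibility

The shipped analyses use a 10 Mb genome (1000 × 10 kb bins), 500-cell
populations, 50× per-bin coverage, 500 expected reads per always-firing
origin, and 2000-fiber combing samples — sizes chosen so every analysis
exhibits its qualitative behavior clearly while any script or test runs in
seconds. All randomness flows through explicit integer seeds;
`rerep-kit run` writes a manifest with the config hash, seed and per-file
checksums, and identical config + seed reproduces byte-identical outputs.

Passing the shipped checks demonstrates internal consistency of the
simulator and the correctness of the analysis operations on data with the
study's statistical structure. It does not establish performance on real
sequencing data, which add mappability artifacts, GC bias, copy-number
variation and batch effects that the generator deliberately omits.
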