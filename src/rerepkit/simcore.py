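"""Stochastic simulator of origin licensing, firing, re-firing and labeling.

The simulator produces every input the downstream analysis stages consume:
binned copy-number tracks for G1 / asynchronous-S / re-replicating cells,
per-origin nascent-strand read counts, DNA-fiber fork measurements, and
fragment strand-substitution states with their density-gradient profiles.

Model sketch
------------
A genome is a single chromosome of ``n_bins`` fixed-width bins carrying a
smooth replication-timing field in [0, 1] (0 = earliest) and a euchromatin
score anti-correlated with timing. Origins are placed with intensity
``exp(kappa * (1 - timing))`` so that licensing (and the licensing-weight
proxy for CDT1/pre-RC density) is skewed toward early-replicating chromatin.

In a *normal* S phase each competent origin fires with a fixed probability at
a time proportional to its local timing value; forks extend bidirectionally
at constant speed and each cell is harvested at a uniform point of S-phase
progress, so early-replicating bins are duplicated in more cells. In
*rereplication* mode the first round runs to completion and the same origin
pool then re-fires with probability ``relicense_prob * weight *
exp(-beta * timing)``: the early-firing bias of re-initiation is the
``beta`` knob. *stress* mode models replication stress: dormant origins gain
a firing probability and forks are slowed.

BrdU substitution is tracked per bin on a representative (newest) duplex:
the first labeled passage of a fork marks one strand (heavy-light, HL), any
re-replication of already-replicated DNA marks both (heavy-heavy, HH). The
HH fraction therefore equals the re-replicated template fraction exactly,
which is what the CsCl-gradient readout is designed to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import BinningMismatchError, EmptyInputError, InvalidConfigError

MODES = ("normal", "rereplication", "stress")
FRAGMENT_CLASSES = ("LL", "HL", "HH")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomeModel:
    """Binned synthetic genome with per-bin timing and euchromatin scores."""

    chrom_name: str
    n_bins: int
    bin_width: int
    timing: np.ndarray      # in [0, 1]; 0 = earliest-replicating
    euchromatin: np.ndarray  # eigen-score proxy; positive = euchromatin
    seed: int

    @property
    def length(self) -> int:
        return self.n_bins * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_of(self, positions_bp) -> np.ndarray:
        idx = np.asarray(positions_bp, dtype=np.int64) // self.bin_width
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass(frozen=True)
class OriginSet:
    """Licensed replication origins with CDT1/pre-RC licensing-weight proxies."""

    positions: np.ndarray          # bp, strictly increasing
    licensing_weight: np.ndarray   # nonnegative, mean ~ 1
    is_dormant: np.ndarray         # dormant: fires only under stress

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SimParams:
    """Simulation knobs; probabilities apply per label window / per round, not per minute."""

    fork_speed_kb_per_min: float = 1.5
    stall_prob: float = 0.05            # per fork per label window
    fire_prob_normal: float = 0.6       # per competent origin per S phase
    rerep_bias: float = 2.0             # beta: early-preference of re-firing
    relicense_prob: float = 0.3         # per origin per re-round
    licensing_skew: float = 2.0         # kappa used when placing origins
    label_minutes_first: float = 20.0
    label_minutes_second: float = 20.0
    cells: int = 500
    depth: float = 500.0                # expected reads per always-firing origin
    s_phase_minutes: float = 480.0
    rerep_minutes: float = 60.0         # re-round fork-extension window
    firing_jitter: float = 0.05         # SD of firing-time jitter (S-phase fraction)
    fiber_noise_cv: float = 0.05        # optical measurement noise on fiber lengths
    fiber_mean_iod_kb: float = 100.0    # mean inter-origin distance on fibers
    fiber_extra_origins: float = 0.7    # Poisson mean of extra origins per fiber
    dormant_fire_eps: float = 0.01      # dormant firing prob outside stress
    stress_dormant_fire_prob: float = 0.7
    stress_speed_factor: float = 0.5
    rerep_delay_frac: float = 1.0       # fraction of round 1 completed before re-firing
    seed: int = 0

    def validate(self) -> None:
        for name in ("stall_prob", "fire_prob_normal", "relicense_prob",
                     "dormant_fire_eps", "stress_dormant_fire_prob", "rerep_delay_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        for name in ("fork_speed_kb_per_min", "s_phase_minutes", "rerep_minutes"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.rerep_bias < 0:
            raise InvalidConfigError("rerep_bias must be >= 0")
        if self.cells < 1:
            raise InvalidConfigError("cells must be >= 1")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass
class PopulationResult:
    """Aggregated outcome of a simulated cell population."""

    mode: str
    cells: int
    copy_per_bin: np.ndarray        # mean copy number over cells
    firing_normal: np.ndarray       # per-origin count of first-round initiations
    firing_re: np.ndarray           # per-origin count of re-round initiations
    class_counts: np.ndarray        # (n_bins, 3): LL / HL / HH fragment counts
    copy_min: int
    copy_max: int
    mean_rep_frac: np.ndarray | None = None
    """Realized per-bin replication timing: mean over cells of the bin's
    replication time as a fraction of that cell's S phase (normal/stress
    modes). This is the simulator's ground truth for timing inference; it
    differs from the latent origin firing-time field wherever bins are
    replicated passively by forks from neighboring origins."""

    @property
    def hh_template_fraction(self) -> float:
        """Fraction of fragments whose template was re-replicated (== HH share)."""
        total = self.class_counts.sum()
        return float(self.class_counts[:, 2].sum() / total) if total else 0.0

    def fragments(self) -> pd.DataFrame:
        """Long-form fragment table: bin_index, strand1_labeled, strand2_labeled, count."""
        flags = [(False, False), (True, False), (True, True)]
        rows = []
        for j, (s1, s2) in enumerate(flags):
            counts = self.class_counts[:, j]
            nz = np.nonzero(counts)[0]
            for b in nz:
                rows.append((int(b), s1, s2, int(counts[b])))
        return pd.DataFrame(rows, columns=["bin_index", "strand1_labeled",
                                           "strand2_labeled", "count"])

    def fragment_class_totals(self) -> dict:
        tot = self.class_counts.sum(axis=0)
        return dict(zip(FRAGMENT_CLASSES, (int(tot[0]), int(tot[1]), int(tot[2]))))


@dataclass
class FiberSet:
    """Combed-fiber measurements: per-origin left/right labeled fork lengths (kb)."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["fiber_id", "origin_pos_kb", "left_kb", "right_kb"]))
    label_minutes: float = 40.0

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# genome and origins


def build_genome(n_bins: int, bin_width: int, *, coupling: float = 1.0,
                 smooth_bins: float = 50.0, seed: int = 0,
                 chrom_name: str = "chrSim") -> GenomeModel:
    """Generate a synthetic genome with a smooth timing field.

    The timing field is low-pass-filtered Gaussian noise rescaled to [0, 1],
    giving contiguous early/late replication domains. The euchromatin score
    is the negated standardized timing plus noise whose amplitude shrinks as
    ``coupling`` -> 1; at coupling 0 the two tracks are independent.
    """
    if n_bins < 1 or bin_width < 1:
        raise InvalidConfigError("n_bins and bin_width must be >= 1")
    if not 0.0 <= coupling <= 1.0:
        raise InvalidConfigError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(n_bins)
    smooth = gaussian_filter1d(raw, sigma=smooth_bins, mode="wrap") if n_bins > 1 else raw
    span = smooth.max() - smooth.min()
    timing = (smooth - smooth.min()) / span if span > 0 else np.full(n_bins, 0.5)
    sd = timing.std()
    z = (timing - timing.mean()) / sd if sd > 0 else np.zeros(n_bins)
    noise = rng.standard_normal(n_bins)
    if coupling <= 0.0:
        euchromatin = noise
    else:
        euchromatin = -z + ((1.0 - coupling) / coupling) * noise
    return GenomeModel(chrom_name, int(n_bins), int(bin_width),
                       timing, euchromatin, int(seed))


def place_origins(genome: GenomeModel, density_per_mb: float, *,
                  skew: float = 0.0, dormant_fraction: float = 0.0,
                  seed: int = 0) -> OriginSet:
    """Place origins with early-skewed intensity ``exp(skew * (1 - timing))``.

    Licensing weights follow the same intensity (normalized to mean 1) with
    mild lognormal origin-to-origin variation, mimicking graded pre-RC density.
    """
    if density_per_mb <= 0:
        raise InvalidConfigError("density_per_mb must be > 0")
    if not 0.0 <= dormant_fraction <= 1.0:
        raise InvalidConfigError("dormant_fraction must be in [0, 1]")
    n = int(round(density_per_mb * genome.length / 1e6))
    if n < 1:
        warnings.warn("expected origin count < 1; returning empty OriginSet")
        empty = np.array([], dtype=np.int64)
        return OriginSet(empty, np.array([]), np.array([], dtype=bool))
    rng = np.random.default_rng(seed)
    intensity = np.exp(skew * (1.0 - genome.timing))
    p = intensity / intensity.sum()
    bins = rng.choice(genome.n_bins, size=n, p=p)
    pos = bins.astype(np.int64) * genome.bin_width + rng.integers(0, genome.bin_width, size=n)
    pos = np.unique(pos)                      # sorted, strictly increasing
    bins = pos // genome.bin_width
    w = intensity[bins] / intensity.mean()
    w = w * rng.lognormal(mean=0.0, sigma=0.2, size=len(pos))
    dormant = rng.random(len(pos)) < dormant_fraction
    return OriginSet(pos, w, dormant)


# ---------------------------------------------------------------------------
# population simulation

_LL, _HL, _HH = 0, 1, 2


def _fire_probabilities(origins: OriginSet, params: SimParams, mode: str) -> np.ndarray:
    p = np.full(len(origins), params.fire_prob_normal)
    if mode == "stress":
        p[origins.is_dormant] = params.stress_dormant_fire_prob
    else:
        p[origins.is_dormant] = params.dormant_fire_eps
    return p


def simulate_population(genome: GenomeModel, origins: OriginSet, params: SimParams,
                        mode: str = "normal", *, s_progress: float | None = None,
                        rerep_progress: float | None = None) -> PopulationResult:
    """Simulate a population of cells and aggregate copy number and fragments.

    ``s_progress`` / ``rerep_progress`` pin the harvest point within the
    (re-)round for every cell instead of drawing it uniformly — useful for
    forcing fully duplicated or fully re-replicated populations.
    """
    if mode not in MODES:
        raise InvalidConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    params.validate()
    if len(origins) == 0:
        raise EmptyInputError("cannot simulate a population without origins")
    rng = np.random.default_rng(params.seed)
    n_bins, n_orig = genome.n_bins, len(origins)
    speed = params.fork_speed_kb_per_min * (params.stress_speed_factor if mode == "stress" else 1.0)
    t_orig = genome.timing[genome.bin_of(origins.positions)]
    # fork travel time from each origin to each bin, in S-phase fraction units
    dist_bp = np.abs(genome.bin_centers[None, :] - origins.positions[:, None].astype(float))
    travel = dist_bp / (speed * 1000.0) / params.s_phase_minutes

    copy_sum = np.zeros(n_bins)
    class_counts = np.zeros((n_bins, 3), dtype=np.int64)
    firing_normal = np.zeros(n_orig, dtype=np.int64)
    firing_re = np.zeros(n_orig, dtype=np.int64)
    copy_min, copy_max = np.inf, -np.inf

    # harvest points: stratified uniform grid over (re-)round progress, in
    # shuffled order — a quasi-Monte-Carlo rendering of the uniform
    # asynchronous-harvest assumption that removes sampling noise in the
    # population's S-phase progress distribution
    harvest = rng.permutation((np.arange(params.cells) + 0.5) / params.cells)
    rep_frac_sum = np.zeros(n_bins)

    p_fire = _fire_probabilities(origins, params, mode)
    w_norm = origins.licensing_weight / max(origins.licensing_weight.mean(), 1e-12)
    p_re = np.clip(params.relicense_prob * w_norm * np.exp(-params.rerep_bias * t_orig), 0.0, 1.0)
    p_re[origins.is_dormant] = np.minimum(p_re[origins.is_dormant], params.dormant_fire_eps)
    rerep_reach_bins = params.rerep_minutes * speed * 1000.0 / genome.bin_width

    for cell in range(params.cells):
        if mode in ("normal", "stress"):
            fired = rng.random(n_orig) < p_fire
            if not fired.any():
                fired[np.argmin(t_orig)] = True
            t_fire = np.clip(t_orig[fired] + rng.normal(0.0, params.firing_jitter,
                                                        fired.sum()), 0.0, 1.0)
            rep_time = np.min(t_fire[:, None] + travel[fired], axis=0)
            rep_frac_sum += rep_time / rep_time.max()
            u = harvest[cell] if s_progress is None else float(s_progress)
            replicated = rep_time <= u * rep_time.max()
            copy = 1 + replicated.astype(np.int64)
            firing_normal += fired
            class_counts[replicated, _HL] += 1
            class_counts[~replicated, _LL] += 1
        else:
            # round 1 complete (re-initiation only allowed after rerep_delay_frac
            # of the first round; the aggregate outcome is a fully duplicated,
            # fully HL genome at re-round start)
            copy = np.full(n_bins, 2, dtype=np.int64)
            refired = rng.random(n_orig) < p_re
            firing_normal += 1          # every origin region completed round 1
            firing_re += refired
            # re-initiations follow the normal timing order but the population
            # is harvested late in the re-round, after every re-fired origin
            # has run its extension window; per-event fork lifetimes vary
            # independently of timing so that beta alone sets the early bias
            if rerep_progress is None:
                extent = 0.5 + 0.5 * rng.random(refired.sum())
            else:
                extent = np.full(refired.sum(), float(rerep_progress))
            rerep_cover = np.zeros(n_bins, dtype=np.int64)
            centers = genome.bin_of(origins.positions[refired])
            reach = extent * rerep_reach_bins
            for c, r in zip(centers, reach):
                lo = max(0, int(np.floor(c - r)))
                hi = min(n_bins - 1, int(np.ceil(c + r)))
                rerep_cover[lo:hi + 1] += 1
            copy = copy + rerep_cover
            hh = rerep_cover > 0
            class_counts[hh, _HH] += 1
            class_counts[~hh, _HL] += 1
        copy_sum += copy
        copy_min = min(copy_min, int(copy.min()))
        copy_max = max(copy_max, int(copy.max()))

    mean_rep = rep_frac_sum / params.cells if mode in ("normal", "stress") else None
    return PopulationResult(mode, params.cells, copy_sum / params.cells,
                            firing_normal, firing_re, class_counts,
                            int(copy_min), int(copy_max), mean_rep)


# ---------------------------------------------------------------------------
# nascent-strand reads and coverage tracks


def simulate_nascent_reads(origins: OriginSet, population: PopulationResult,
                           depth: float, seed: int = 0, *,
                           which_round: str = "normal") -> np.ndarray:
    """Per-origin NS-seq read counts ~ Poisson(depth * firing frequency).

    ``which_round='normal'`` counts first-round initiations (HL nascent DNA);
    ``'re'`` counts only re-round initiations on already-replicated template
    (HH nascent DNA).
    """
    if depth <= 0:
        raise InvalidConfigError("depth must be > 0")
    if which_round not in ("normal", "re"):
        raise InvalidConfigError("which_round must be 'normal' or 're'")
    firing = population.firing_normal if which_round == "normal" else population.firing_re
    if len(firing) != len(origins):
        raise BinningMismatchError("origin set does not match population firing counts")
    freq = firing / population.cells
    rng = np.random.default_rng(seed)
    return rng.poisson(depth * freq)


def simulate_coverage(copy_per_bin: np.ndarray, depth_per_bin: float,
                      seed: int = 0) -> np.ndarray:
    """Sequencing coverage: Poisson reads proportional to local copy number."""
    if depth_per_bin <= 0:
        raise InvalidConfigError("depth_per_bin must be > 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(depth_per_bin * np.asarray(copy_per_bin, dtype=float)).astype(float)


def licensing_track(genome: GenomeModel, origins: OriginSet, *,
                    peak_sd_bins: float = 1.5, background: float = 0.1,
                    seed: int = 0) -> np.ndarray:
    """A CDT1-like binding track: Gaussian bumps at origins scaled by licensing weight."""
    rng = np.random.default_rng(seed)
    sig = np.zeros(genome.n_bins)
    bins = genome.bin_of(origins.positions)
    np.add.at(sig, bins, origins.licensing_weight)
    sig = gaussian_filter1d(sig, sigma=peak_sd_bins, mode="constant")
    return sig + background * rng.random(genome.n_bins)


# ---------------------------------------------------------------------------
# fibers


def _fork_lengths(n: int, speed: float, total_minutes: float, stall_prob: float,
                  noise_cv: float, rng: np.random.Generator) -> np.ndarray:
    """One side's labeled-track lengths under the uniform-stall model."""
    full = speed * total_minutes
    length = np.full(n, full)
    stalled = rng.random(n) < stall_prob
    length[stalled] = full * rng.random(stalled.sum())   # stall at a uniform time
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        length = length * rng.lognormal(-0.5 * sigma ** 2, sigma, n)
    return length


def simulate_fibers(origins: OriginSet, params: SimParams, n_fibers: int,
                    seed: int = 0, *, stall_prob: float | None = None) -> FiberSet:
    """Simulate combed fibers with bidirectional labeled forks per origin.

    Each side extends for the full double-label window unless it stalls
    (probability ``stall_prob`` per side per window) at a uniform time;
    multiplicative lognormal noise models optical measurement error. Fibers
    may carry several origins (1 + Poisson extra), spaced exponentially, so
    inter-origin distances are measurable.
    """
    if n_fibers < 0:
        raise InvalidConfigError("n_fibers must be >= 0")
    sp = params.stall_prob if stall_prob is None else stall_prob
    total_min = params.label_minutes_first + params.label_minutes_second
    if n_fibers == 0:
        return FiberSet(label_minutes=total_min)
    rng = np.random.default_rng(seed)
    n_per_fiber = 1 + rng.poisson(params.fiber_extra_origins, n_fibers)
    rows = []
    for fid, k in enumerate(n_per_fiber):
        gaps = rng.exponential(params.fiber_mean_iod_kb, k - 1) if k > 1 else np.array([])
        pos = 50.0 * rng.random() + np.concatenate([[0.0], np.cumsum(gaps)])
        left = _fork_lengths(k, params.fork_speed_kb_per_min, total_min, sp,
                             params.fiber_noise_cv, rng)
        right = _fork_lengths(k, params.fork_speed_kb_per_min, total_min, sp,
                              params.fiber_noise_cv, rng)
        for j in range(k):
            rows.append((fid, pos[j], left[j], right[j]))
    df = pd.DataFrame(rows, columns=["fiber_id", "origin_pos_kb", "left_kb", "right_kb"])
    return FiberSet(df, label_minutes=total_min)


def stall_model_asymmetry_mc(stall_prob: float, threshold: float = 0.30,
                             n_draws: int = 1_000_000, seed: int = 12345) -> float:
    """Independent Monte-Carlo of the stall model's asymmetric-fork prevalence.

    Brute-force oracle: draw left/right lengths from the same uniform-stall
    model (unit speed and time, no optical noise) and count forks whose
    relative length difference |L-R|/max(L,R) exceeds the threshold.
    """
    rng = np.random.default_rng(seed)
    left = np.ones(n_draws)
    right = np.ones(n_draws)
    ls = rng.random(n_draws) < stall_prob
    rs = rng.random(n_draws) < stall_prob
    left[ls] = rng.random(ls.sum())
    right[rs] = rng.random(rs.sum())
    mx = np.maximum(left, right)
    return float(np.mean(np.abs(left - right) / mx > threshold))


# ---------------------------------------------------------------------------
# density gradient (Meselson–Stahl readout)

DEFAULT_DENSITIES = (1.70, 1.755, 1.81)  # g/cm^3 for LL, HL, HH duplex DNA


def fragment_mixture(n: int, hh_fraction: float, *, ll_fraction: float = 0.0) -> dict:
    """Deterministic fragment-class totals for a given re-replicated share."""
    if not 0.0 <= hh_fraction <= 1.0 or not 0.0 <= ll_fraction <= 1.0 - hh_fraction:
        raise InvalidConfigError("fractions must be in [0, 1] and sum to <= 1")
    n_hh = int(round(n * hh_fraction))
    n_ll = int(round(n * ll_fraction))
    return {"LL": n_ll, "HL": n - n_hh - n_ll, "HH": n_hh}


def simulate_gradient(class_totals: dict, *, n_fractions: int = 20,
                      densities: tuple = DEFAULT_DENSITIES, sd: float = 0.005,
                      seed: int = 0) -> pd.DataFrame:
    """CsCl gradient fractionation of a fragment population.

    Each fragment's buoyant density is Normal(rho_class, sd); fragments are
    binned into ``n_fractions`` equal-width fractions spanning the class
    densities +/- 4 sd (draws outside are clipped into the end fractions, so
    total mass is conserved). Returns a per-fraction table with the class
    composition and fraction centers.
    """
    rho_ll, rho_hl, rho_hh = densities
    if not rho_ll < rho_hl < rho_hh:
        raise InvalidConfigError("densities must be strictly ordered LL < HL < HH")
    counts = {k: int(class_totals.get(k, 0)) for k in FRAGMENT_CLASSES}
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("gradient requires at least one fragment")
    lo, hi = rho_ll - 4 * sd, rho_hh + 4 * sd
    edges = np.linspace(lo, hi, n_fractions + 1)
    width = edges[1] - edges[0]
    # keep class densities strictly inside fractions: a density on a boundary
    # would split a sharp band across two fractions
    if np.min(np.abs(edges[:, None] - np.asarray(densities)[None, :])) < 1e-9 * width:
        edges = edges - width / 2.0
    lo, hi = edges[0], edges[-1]
    rng = np.random.default_rng(seed)
    out = {}
    for cls, rho in zip(FRAGMENT_CLASSES, densities):
        n = counts[cls]
        draws = rng.normal(rho, sd, n) if sd > 0 else np.full(n, rho)
        draws = np.clip(draws, lo, hi - 1e-12)
        out[cls], _ = np.histogram(draws, bins=edges)
    df = pd.DataFrame({
        "fraction": np.arange(1, n_fractions + 1),
        "density": 0.5 * (edges[:-1] + edges[1:]),
        "mass_LL": out["LL"], "mass_HL": out["HL"], "mass_HH": out["HH"],
    })
    df["mass_total"] = df[["mass_LL", "mass_HL", "mass_HH"]].sum(axis=1)
    df.attrs["densities"] = tuple(densities)
    df.attrs["sd"] = sd
    return df


def class_window_mass(profile: pd.DataFrame, cls: str) -> float:
    """Share of total gradient mass in the fractions nearest to one class density.

    A fraction belongs to the window of the class whose characteristic density
    is closest to the fraction center — the way gradient fractions are pooled
    into LL / HL / HH windows experimentally.
    """
    if cls not in FRAGMENT_CLASSES:
        raise InvalidConfigError(f"unknown fragment class {cls!r}")
    densities = np.asarray(profile.attrs["densities"])
    nearest = np.argmin(np.abs(profile["density"].to_numpy()[:, None] - densities[None, :]),
                        axis=1)
    target = FRAGMENT_CLASSES.index(cls)
    total = profile["mass_total"].sum()
    if total == 0:
        return 0.0
    return float(profile.loc[nearest == target, "mass_total"].sum() / total)
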