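"""End-to-end pipeline: simulate -> timing -> origin usage -> fibers -> domains.

Each stage writes its outputs under the configured output directory and a
manifest (config hash, seed, per-file checksums) records provenance. Stages
never mutate another stage's outputs; a failing stage aborts the run with
the stage name while earlier outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, fibers, origin_usage, simcore, timing
from .config import PipelineConfig, config_to_dict
from .io import Track, write_bed, write_bedgraph, write_fibers

logger = logging.getLogger("rerepkit")

CONDITIONS = ("control_hl", "mln_hl", "mln_hh", "stress_hl")


def _seed(base: int, k: int) -> int:
    return (base * 1000 + k) % (2 ** 31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the report bundle (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    state: dict = {}
    for stage, fn in [("simulate", _stage_simulate), ("timing", _stage_timing),
                      ("origins", _stage_origins), ("fibers", _stage_fibers),
                      ("domains", _stage_domains)]:
        logger.info("stage %s: starting (seed=%d)", stage, cfg.seed)
        try:
            report[stage] = fn(cfg, state, out)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    cfg_dict = config_to_dict(cfg)
    cfg_dict.pop("out_dir", None)    # provenance covers the science, not the paths
    manifest = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report


# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    g, o, p = cfg.genome, cfg.origins, cfg.simulation
    genome = simcore.build_genome(g.n_bins, g.bin_width, coupling=g.coupling,
                                  smooth_bins=g.smooth_bins, seed=_seed(cfg.seed, 1))
    origins = simcore.place_origins(genome, o.density_per_mb, skew=o.skew,
                                    dormant_fraction=o.dormant_fraction,
                                    seed=_seed(cfg.seed, 2))
    pops = {}
    for k, mode in enumerate(("normal", "rereplication", "stress")):
        pops[mode] = simcore.simulate_population(
            genome, origins, p.with_(seed=_seed(cfg.seed, 10 + k)), mode)
    depth = cfg.analysis.depth_per_bin
    # completed-S (G2-like) control: the baseline for amplification scoring,
    # free of the asynchronous population's timing slope
    pop_g2 = simcore.simulate_population(genome, origins,
                                         p.with_(seed=_seed(cfg.seed, 10)),
                                         "normal", s_progress=1.0)
    tracks = {
        "g1": simcore.simulate_coverage(np.ones(genome.n_bins), depth, _seed(cfg.seed, 20)),
        "s_async": simcore.simulate_coverage(pops["normal"].copy_per_bin, depth,
                                             _seed(cfg.seed, 21)),
        "s_complete": simcore.simulate_coverage(pop_g2.copy_per_bin, depth,
                                                _seed(cfg.seed, 23)),
        "rerep": simcore.simulate_coverage(pops["rereplication"].copy_per_bin, depth,
                                           _seed(cfg.seed, 22)),
    }
    for name, vals in tracks.items():
        write_bedgraph(Track(genome.chrom_name, np.arange(genome.n_bins) * g.bin_width,
                             (np.arange(genome.n_bins) + 1) * g.bin_width, vals),
                       out / f"{name}.bedgraph")
    write_bedgraph(Track(genome.chrom_name, np.arange(genome.n_bins) * g.bin_width,
                         (np.arange(genome.n_bins) + 1) * g.bin_width,
                         genome.euchromatin), out / "euchromatin.bedgraph")
    reads = {
        "control_hl": simcore.simulate_nascent_reads(origins, pops["normal"], p.depth,
                                                     _seed(cfg.seed, 30)),
        "mln_hl": simcore.simulate_nascent_reads(origins, pops["rereplication"], p.depth,
                                                 _seed(cfg.seed, 31)),
        "mln_hh": simcore.simulate_nascent_reads(origins, pops["rereplication"], p.depth,
                                                 _seed(cfg.seed, 32), which_round="re"),
        "stress_hl": simcore.simulate_nascent_reads(origins, pops["stress"], p.depth,
                                                    _seed(cfg.seed, 33)),
    }
    intervals = pd.DataFrame({
        "chrom": genome.chrom_name,
        "start": origins.positions - 500,
        "end": origins.positions + 500,
    })
    for cond, counts in reads.items():
        bed = intervals.copy()
        bed["name"] = [f"origin_{i}" for i in range(len(origins))]
        bed["score"] = counts.astype(float)
        write_bed(bed, out / f"origins_{cond}.bed")
    fib = {
        "control": simcore.simulate_fibers(origins, p, cfg.analysis.n_fibers,
                                           _seed(cfg.seed, 40)),
        "treated": simcore.simulate_fibers(origins, p, cfg.analysis.n_fibers,
                                           _seed(cfg.seed, 41),
                                           stall_prob=cfg.analysis.treated_stall_prob),
    }
    for name, fs in fib.items():
        write_fibers(fs.records, out / f"fibers_{name}.tsv")
    grad = simcore.simulate_gradient(pops["rereplication"].fragment_class_totals(),
                                     seed=_seed(cfg.seed, 50))
    grad.to_csv(out / "gradient.tsv", sep="\t", index=False)
    state.update(genome=genome, origins=origins, pops=pops, tracks=tracks,
                 reads=reads, intervals=intervals, fibersets=fib, gradient=grad)
    return {
        "n_origins": len(origins),
        "hh_template_fraction": pops["rereplication"].hh_template_fraction,
        "hh_window_mass": simcore.class_window_mass(grad, "HH"),
        "max_copy_normal": pops["normal"].copy_max,
        "max_copy_rereplication": pops["rereplication"].copy_max,
    }


def _stage_timing(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    genome = state["genome"]
    bw = cfg.genome.bin_width
    mk = lambda v: Track(genome.chrom_name, np.arange(genome.n_bins) * bw,
                         (np.arange(genome.n_bins) + 1) * bw, v)
    c = cfg.analysis.pseudocount
    async_ratio = timing.log2_ratio(mk(state["tracks"]["s_async"]),
                                    mk(state["tracks"]["g1"]), c,
                                    smooth_window=20, smooth_kind="gaussian")
    control = timing.log2_ratio(mk(state["tracks"]["s_complete"]),
                                mk(state["tracks"]["g1"]), c)
    rerep = timing.log2_ratio(mk(state["tracks"]["rerep"]), mk(state["tracks"]["g1"]), c)
    write_bedgraph(rerep.track, out / "rerep_log2_ratio.bedgraph")
    groups6 = timing.stratify_by_range_percentile(async_ratio, "six_range")
    groups4 = timing.stratify_by_range_percentile(async_ratio, "four_equal")
    bed = pd.DataFrame({"chrom": genome.chrom_name,
                        "start": np.arange(genome.n_bins) * bw,
                        "end": (np.arange(genome.n_bins) + 1) * bw,
                        "name": groups6.labels})
    write_bed(bed, out / "timing_groups.bed")
    amp = timing.amplification_scores(rerep, control, groups4)
    amp.summary.to_csv(out / "amplification_by_group.tsv", sep="\t", index=False)
    state.update(control_ratio=control, rerep_ratio=rerep,
                 groups6=groups6, groups4=groups4)
    med = amp.group_medians()
    return {"group_medians": {k: float(v) for k, v in med.items()}}


def _stage_origins(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    a = cfg.analysis
    table = origin_usage.OriginUsageTable(state["intervals"], dict(state["reads"]))
    pairs = origin_usage.pair_conditions(table, "control_hl", "mln_hh")
    pairs.to_csv(out / "pairs_control_vs_mln_hh.tsv", sep="\t", index=False)
    frac = origin_usage.ratio_fractions(pairs, a.n_fractions, a.peak_small,
                                        a.peak_large_min, a.peak_small[0])
    frac.table.to_csv(out / "ratio_fractions.tsv", sep="\t", index=False)
    stress_pairs = origin_usage.pair_conditions(table, "control_hl", "stress_hl")
    dormant = origin_usage.detect_dormant(stress_pairs, a.dormant_low, a.dormant_high)
    if len(dormant.dormant):
        write_bed(dormant.dormant[["chrom", "start", "end"]], out / "dormant_origins.bed")
    genome = state["genome"]
    obins, n_drop = timing.assign_bins_to_positions(state["origins"].positions,
                                                    cfg.genome.bin_width, genome.n_bins)
    strat = origin_usage.timing_stratified_pairs(
        pairs.iloc[:len(obins)], state["groups6"].labels[obins],
        state["groups6"].group_names, n_fractions=a.n_fractions,
        small=a.peak_small, large_min=a.peak_large_min, min_count=a.peak_small[0])
    shift = {g: d["mean_log2_ratio"] for g, d in strat.items()}
    state.update(pairs=pairs, stress_pairs=stress_pairs, dormant=dormant)
    return {"n_classified": frac.n_classified, "n_excluded": frac.n_excluded,
            "dormant_share_stress": dormant.share,
            "mean_log2_ratio_by_group": shift, "origins_dropped": n_drop}


def _stage_fibers(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    thr = cfg.analysis.asymmetry_threshold
    res = {}
    summaries = {}
    for name, fs in state["fibersets"].items():
        s = fibers.asymmetry_summary(fs, thr)
        summaries[name] = s
        res[name] = {"n_forks": s.n_forks, "pct_asymmetric": s.percentage,
                     "median_rate_kb_min": float(np.median(fibers.fork_rates(fs))),
                     "median_iod_kb": float(np.median(fibers.inter_origin_distances(fs)))}
    u, p_mw = fibers.rank_sum_test(fibers.fork_rates(state["fibersets"]["control"]),
                                   fibers.fork_rates(state["fibersets"]["treated"]))
    sc, st = summaries["control"], summaries["treated"]
    chi2, p_chi = fibers.two_by_two_chisq(sc.n_asymmetric, sc.n_forks - sc.n_asymmetric,
                                          st.n_asymmetric, st.n_forks - st.n_asymmetric)
    res["tests"] = {"mannwhitney_U": u, "mannwhitney_p": p_mw,
                    "chi2": chi2, "chi2_p": p_chi}
    with open(out / "fiber_summary.json", "w") as fh:
        json.dump(res, fh, indent=2)
    return res


def _stage_domains(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    a = cfg.analysis
    genome = state["genome"]
    rerep_track = state["rerep_ratio"].track
    domains = chromatin.segment_domains(rerep_track, a.background_quantile,
                                        a.min_gap_bp, a.min_size_bp)
    result: dict = {"n_domains": len(domains), "mean_size_kb": domains.mean_size_bp / 1000}
    if len(domains) >= 4:
        domains = chromatin.quartile_stratify(domains)
        bed = domains.intervals.rename(columns={"quartile": "name",
                                                "peak_height": "score"})
        write_bed(bed[["chrom", "start", "end", "name", "score"]], out / "domains.bed")
        eu = state["genome"].euchromatin
        eu_iv = chromatin.segment_domains(
            Track(genome.chrom_name, rerep_track.starts, rerep_track.ends, eu), 0.5)
        rep = chromatin.inc_ratio(domains.intervals, eu_iv.intervals)
        result["inc_ratio_vs_euchromatin"] = rep.inc_ratio
    eig = chromatin.eigen_correlation(
        rerep_track, Track(genome.chrom_name, rerep_track.starts, rerep_track.ends,
                           genome.euchromatin))
    eig.group_summary.to_csv(out / "eigen_by_abundance_group.tsv", sep="\t", index=False)
    result["eigen_pearson_r"] = eig.pearson_r
    sig = simcore.licensing_track(genome, state["origins"], seed=_seed(cfg.seed, 60))
    obins, _ = timing.assign_bins_to_positions(state["origins"].positions,
                                               cfg.genome.bin_width, genome.n_bins)
    prof = chromatin.anchor_profile(
        Track(genome.chrom_name, rerep_track.starts, rerep_track.ends, sig),
        state["origins"].positions, a.flank_bp,
        groups=state["groups6"].labels[obins],
        group_names=state["groups6"].group_names,
        n_random=len(obins), seed=_seed(cfg.seed, 61))
    pd.DataFrame({"offset_bp": prof.offsets_bp, "mean_signal": prof.mean_profile,
                  **{f"group_{g}": v for g, v in prof.group_profiles.items()},
                  "random": prof.random_profile}).to_csv(
        out / "origin_anchor_profile.tsv", sep="\t", index=False)
    result["anchor_group_scores"] = {g: float(v) for g, v in prof.group_scores.items()}
    return result
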