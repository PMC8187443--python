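"""Pipeline configuration: YAML schema, defaults and validation.

A single YAML file drives the whole pipeline. Sections:

``genome``      n_bins, bin_width, coupling, smooth_bins
``origins``     density_per_mb, skew, dormant_fraction
``simulation``  SimParams fields (cells, depth, fire_prob_normal, ...)
``analysis``    asymmetry_threshold (0.30), peak_small (250, 400),
                peak_large_min (400), n_fractions (10), timing_scheme,
                pseudocount, dormant_low / dormant_high,
                background_quantile, min_gap_bp, min_size_bp, flank_bp
``out_dir``     output directory
``seed``        global seed; per-stage seeds are derived from it

All thresholds are validated before any stage runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import InvalidConfigError
from .simcore import SimParams


@dataclass
class GenomeConfig:
    n_bins: int = 1000
    bin_width: int = 10_000
    coupling: float = 1.0
    smooth_bins: float = 20.0


@dataclass
class OriginConfig:
    density_per_mb: float = 30.0
    skew: float = 2.0
    dormant_fraction: float = 0.15


@dataclass
class AnalysisConfig:
    asymmetry_threshold: float = 0.30
    peak_small: tuple = (250.0, 400.0)
    peak_large_min: float = 400.0
    n_fractions: int = 10
    timing_scheme: str = "six_range"
    pseudocount: float = 1.0
    dormant_low: float = 50.0
    dormant_high: float = 250.0
    background_quantile: float = 0.9
    min_gap_bp: int = 10_000
    min_size_bp: int = 20_000
    flank_bp: int = 50_000
    depth_per_bin: float = 50.0
    n_fibers: int = 1000
    treated_stall_prob: float = 0.4


@dataclass
class PipelineConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    origins: OriginConfig = field(default_factory=OriginConfig)
    simulation: SimParams = field(default_factory=SimParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "rerep_out"
    seed: int = 0

    def validate(self) -> None:
        g = self.genome
        if g.n_bins < 1 or g.bin_width < 1:
            raise InvalidConfigError("genome n_bins and bin_width must be >= 1")
        if not 0.0 <= g.coupling <= 1.0:
            raise InvalidConfigError("genome coupling must be in [0, 1]")
        if self.origins.density_per_mb <= 0:
            raise InvalidConfigError("origin density_per_mb must be > 0")
        if not 0.0 <= self.origins.dormant_fraction <= 1.0:
            raise InvalidConfigError("dormant_fraction must be in [0, 1]")
        self.simulation.validate()
        a = self.analysis
        for name in ("asymmetry_threshold", "peak_large_min", "pseudocount",
                     "dormant_low", "dormant_high", "depth_per_bin"):
            if getattr(a, name) <= 0:
                raise InvalidConfigError(f"analysis.{name} must be > 0")
        if a.n_fractions < 2:
            raise InvalidConfigError("analysis.n_fractions must be >= 2")
        if a.dormant_low >= a.dormant_high:
            raise InvalidConfigError("dormant_low must be < dormant_high")
        if a.timing_scheme not in ("six_range", "four_equal"):
            raise InvalidConfigError("timing_scheme must be six_range or four_equal")


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is AnalysisConfig and "peak_small" in data:
        data = dict(data, peak_small=tuple(data["peak_small"]))
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline config from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    cfg = PipelineConfig(
        genome=_build(GenomeConfig, data.get("genome", {})),
        origins=_build(OriginConfig, data.get("origins", {})),
        simulation=_build(SimParams, data.get("simulation", {})),
        analysis=_build(AnalysisConfig, data.get("analysis", {})),
        out_dir=str(data.get("out_dir", "rerep_out")),
        seed=int(data.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["analysis"]["peak_small"] = list(d["analysis"]["peak_small"])
    return d
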