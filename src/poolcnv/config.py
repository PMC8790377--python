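"""Run configuration: generator, typing, pooling and solver blocks.

All stochastic stages derive their seeds from a single base seed, so a
(config, seed) pair reproduces every artifact byte for byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .simulate import SegmentConfig

__all__ = ["GeneratorConfig", "PipelineConfig", "RunConfig", "load_config"]


def _default_cells_per_type() -> list[int]:
    # 80 cells over 7 types, as uneven as a small patient cohort
    return [12, 12, 12, 11, 11, 11, 11]


@dataclass
class GeneratorConfig:
    """Synthetic-population parameters.

    Defaults model 80 cells in 7 subclonal types over 10,000 bins with 1M
    reads per cell (median ~100 reads/bin, comfortably above the 50-read QC
    floor) and a 2% per-bin copy-flip rate within type.
    """

    T: int = 7
    B: int = 10_000
    cells_per_type: list[int] = field(default_factory=_default_cells_per_type)
    flip_rate: float = 0.02
    reads_per_cell: int = 1_000_000
    seg_config: SegmentConfig = field(default_factory=SegmentConfig)

    @property
    def c(self) -> int:
        return sum(self.cells_per_type)


@dataclass
class PipelineConfig:
    """Typing, pooling and solver parameters.

    ``theta`` is the informative-bin mode-frequency threshold; pool profiles
    default to count space (summed member reads rescaled by pool ploidy);
    the branch-and-bound effort is 100 relaxation passes at the root and 2
    per subsequent node, within a per-instance budget of ``max_nodes`` nodes
    or ``time_limit`` seconds (the coordinate-descent incumbent is returned
    with its certified gap when the budget is hit).
    """

    theta: float = 0.8
    pool_space: str = "count"  # "count" or "profile"
    use_true_cn: bool = False
    sv_rtol: float = 1e-10
    gap_tol: float = 0.0
    root_passes: int = 100
    node_passes: int = 2
    max_nodes: int = 2_000
    time_limit: float = 10.0


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    p_list: list[int] = field(default_factory=lambda: [40, 27])
    k_list: list[float] = field(default_factory=lambda: [0.10, 0.15, 0.20, 0.25, 0.30])
    replicates: int = 3

    def to_dict(self) -> dict:
        return asdict(self)


def _from_mapping(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration, filling defaults for absent blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = dict(raw.pop("generator", {}))
    seg_raw = gen_raw.pop("seg_config", None)
    if seg_raw is not None:
        for key in ("segments_range", "length_range", "amp_levels", "del_levels"):
            if key in seg_raw:
                seg_raw[key] = tuple(seg_raw[key])
        gen_raw["seg_config"] = _from_mapping(SegmentConfig, seg_raw)
    gen = _from_mapping(GeneratorConfig, gen_raw)
    pipe = _from_mapping(PipelineConfig, dict(raw.pop("pipeline", {})))
    cfg = RunConfig(generator=gen, pipeline=pipe)
    if "p_list" in raw:
        cfg.p_list = [int(p) for p in raw.pop("p_list")]
    if "k_list" in raw:
        cfg.k_list = [float(k) for k in raw.pop("k_list")]
    if "replicates" in raw:
        cfg.replicates = int(raw.pop("replicates"))
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return cfg
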