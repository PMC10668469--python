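"""Pipeline configuration: thresholds, age bins, seeds.

Every threshold the analysis applies is collected here so a run can log the
exact settings it resolved.  Validation happens eagerly, before any data is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Age-bin edges in gestational weeks: [8,10), [10,12), ... [16,18), [18,19]
#: with the last bin holding the week-19 samples.
DEFAULT_AGE_BIN_EDGES = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 19.0)


@dataclass
class ReporterConfig:
    min_k: int = 5
    max_k: int = 500
    n_perm: int = 1000
    alpha: float = 0.05
    figure_alpha: float = 0.01


@dataclass
class PipelineConfig:
    alpha_de: float = 0.05
    alpha_corr: float = 0.05
    r_max: float = 0.0
    top_fraction: float = 0.05
    figure_r_cuts: tuple[float, ...] = (-0.7, -0.85)
    alpha_protein: float = 0.05
    reporter: ReporterConfig = field(default_factory=ReporterConfig)
    age_bin_edges: tuple[float, ...] = DEFAULT_AGE_BIN_EDGES
    min_cluster_size: int = 15
    cluster_cut_height: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("alpha_de", "alpha_corr", "alpha_protein"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if not all(c < 0 for c in self.figure_r_cuts):
            raise ValueError("figure r cuts must be negative")
        r = self.reporter
        if isinstance(r, dict):
            r = self.reporter = ReporterConfig(**r)
        if not (0 < r.alpha < 1 and 0 < r.figure_alpha < 1):
            raise ValueError("reporter alphas must be in (0, 1)")
        if not 1 <= r.min_k <= r.max_k:
            raise ValueError("reporter set-size bounds require 1 <= min_k <= max_k")
        if r.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        edges = tuple(float(e) for e in self.age_bin_edges)
        if sorted(edges) != list(edges) or len(set(edges)) != len(edges):
            raise ValueError("age bin edges must be strictly increasing")
        self.age_bin_edges = edges
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "figure_r_cuts" in raw:
        raw["figure_r_cuts"] = tuple(raw["figure_r_cuts"])
    if "age_bin_edges" in raw:
        raw["age_bin_edges"] = tuple(raw["age_bin_edges"])
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
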