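"""Pipeline configuration: a flat, YAML-serializable parameter set."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline.

    Chromatographic defaults follow the reference protocol where one is
    stated (520 spline knots, 0.0005 peak intensity tolerance, FWER
    0.05, phenotype alpha 0.01, four clusters); the rest are the
    package's own documented choices.
    """

    seed: int = 0
    # simulation
    n_points: int = 1500
    n_varieties: int = 8
    n_reps: int = 4
    n_metabolites: int = 20
    effect_size: float = 2.0
    warp_magnitude: float = 0.05
    noise_sd: float = 0.01
    pheno_reps: int = 2
    pheno_noise_sd: float = 1.0
    # preprocessing
    cow_segment_len: int = 30
    cow_slack: int = 8
    spline_knots: int = 520
    peak_tolerance: float = 0.0005
    c1: int | None = None
    c1_fraction: float = 0.5
    # statistics
    fwer_alpha: float = 0.05
    pheno_alpha: float = 0.01
    cluster_k: int = 4
    cluster_restarts: int = 20
    n_permutations: int = 100_000
    # output
    out_dir: str = "phenolome_out"
    treatments: tuple[str, ...] = ("I", "II", "I+II")
    _extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cow_slack >= self.cow_segment_len:
            raise ValueError("cow_slack must be smaller than cow_segment_len")
        if not (0 <= self.cow_slack):
            raise ValueError("cow_slack must be >= 0")
        if self.spline_knots >= self.n_points:
            raise ValueError("spline_knots must be smaller than n_points")
        if self.peak_tolerance < 0:
            raise ValueError("peak_tolerance must be >= 0")
        if not (0 < self.c1_fraction <= 1):
            raise ValueError("c1_fraction must be in (0, 1]")
        if self.c1 is not None and self.c1 < 1:
            raise ValueError("c1 must be >= 1")
        if not (0 < self.fwer_alpha < 1 and 0 < self.pheno_alpha < 1):
            raise ValueError("significance levels must be in (0, 1)")
        if self.cluster_k < 2:
            raise ValueError("cluster_k must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_extra", None)
        d["treatments"] = list(self.treatments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "treatments" in d:
            d["treatments"] = tuple(d["treatments"])
        known = {f for f in cls.__dataclass_fields__ if f != "_extra"}
        extra = {k: d.pop(k) for k in list(d) if k not in known}
        cfg = cls(**d)
        cfg._extra = extra
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
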