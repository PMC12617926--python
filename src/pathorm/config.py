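"""Layered run configuration.

One YAML document carries every stage's knobs (beta, tau, epsilon, hidden
width, sampling ratio, ...); each block is validated by the owning module's
config type before any computation starts.  A single global seed fans out to
per-stage seeds through a stable CRC32-based hash so partial reruns of a
stage are reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_io import ValidationError
from .gae import AdvConfig, EncoderConfig, TrainConfig
from .hetgraph import GraphConfig
from .multiview import MvSolverConfig
from .sampling import SamplerConfig


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class InputPaths:
    fasta: str = ""
    associations: str = ""
    site_semantic: str = ""
    disease_semantic: str = ""
    disease_go: str = ""
    window: int = 21


@dataclass
class FeatureOptions:
    use_alt: bool = False


@dataclass
class EvaluationOptions:
    folds: int = 10


@dataclass
class RunConfig:
    inputs: InputPaths = field(default_factory=InputPaths)
    features: FeatureOptions = field(default_factory=FeatureOptions)
    multiview: MvSolverConfig = field(default_factory=MvSolverConfig)
    graph: GraphConfig = field(default_factory=lambda: GraphConfig(tau=0.5))
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    adversarial: AdvConfig = field(default_factory=AdvConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    sampling: SamplerConfig = field(default_factory=SamplerConfig)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)
    seed: int = 0
    outdir: str = "pathorm_run"

    def __post_init__(self) -> None:
        # fan the global seed out to every stage that owns one
        self.multiview.seed = stage_seed(self.seed, "multiview")
        self.encoder.seed = stage_seed(self.seed, "encoder")
        self.training.seed = stage_seed(self.seed, "training")
        self.sampling.seed = stage_seed(self.seed, "sampling")
        self.graph.seed = stage_seed(self.seed, "graph")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def block(key, typ):
            sub = raw.get(key, {})
            if not isinstance(sub, dict):
                raise ValidationError(f"config block {key!r} must be a mapping")
            try:
                return typ(**sub)
            except TypeError as e:
                raise ValidationError(f"config block {key!r}: {e}") from None

        if "graph" in raw and "tau" not in raw["graph"]:
            raise ValidationError("config block 'graph' must set tau")
        if "graph" not in raw:
            raise ValidationError("config must provide a 'graph' block with tau")
        return cls(
            inputs=block("inputs", InputPaths),
            features=block("features", FeatureOptions),
            multiview=block("multiview", MvSolverConfig),
            graph=block("graph", GraphConfig),
            encoder=block("encoder", EncoderConfig),
            adversarial=block("adversarial", AdvConfig),
            training=block("training", TrainConfig),
            sampling=block("sampling", SamplerConfig),
            evaluation=block("evaluation", EvaluationOptions),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "pathorm_run")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("run config must be a YAML mapping")
        return cls.from_dict(raw)
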