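"""Nested pipeline configuration with YAML round-trip and content hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .datatypes import ValidationError
from .eigen import DEFAULT_N_COMPONENTS
from .mlp import MLPConfig
from .stepwise import StepwiseConfig
from .synth import SynthSpec


@dataclass(frozen=True)
class PreprocessConfig:
    """Target grid size and smoothing mask; ``filter_size=None`` disables smoothing."""

    height: int = 128
    width: int = 128
    filter_size: int | None = 3

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("target size must be positive")
        if self.filter_size is not None and (
            self.filter_size < 1 or self.filter_size % 2 == 0
        ):
            raise ValidationError("filter_size must be odd and >= 1, or None")


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation protocol settings.

    ``global_fit=True`` reproduces the leakier protocol in which the
    eigenspace and the feature selection are fitted once on the full
    dataset instead of per training fold.
    """

    n_folds: int = 10
    seed: int = 0
    global_fit: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthSpec | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pca_k: int = DEFAULT_N_COMPONENTS
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if self.pca_k < 1:
            raise ValidationError("pca_k must be >= 1")

    def to_dict(self) -> dict:
        out = {
            "synth": asdict(self.synth) if self.synth is not None else None,
            "preprocess": asdict(self.preprocess),
            "pca_k": self.pca_k,
            "stepwise": asdict(self.stepwise),
            "mlp": asdict(self.mlp),
            "eval": asdict(self.eval),
        }
        if out["synth"] is not None:
            out["synth"]["class_names"] = list(out["synth"]["class_names"])
            out["synth"]["n_per_class"] = list(out["synth"]["n_per_class"])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        synth = data.get("synth")
        if synth is not None:
            synth = dict(synth)
            if "class_names" in synth:
                synth["class_names"] = tuple(synth["class_names"])
            if "n_per_class" in synth:
                synth["n_per_class"] = tuple(synth["n_per_class"])
            synth = SynthSpec(**synth)
        return cls(
            synth=synth,
            preprocess=PreprocessConfig(**data.get("preprocess", {})),
            pca_k=data.get("pca_k", DEFAULT_N_COMPONENTS),
            stepwise=StepwiseConfig(**data.get("stepwise", {})),
            mlp=MLPConfig(**data.get("mlp", {})),
            eval=EvalConfig(**data.get("eval", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Short content hash: any parameter change changes the hash."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
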