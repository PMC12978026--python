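"""Run configuration: YAML/JSON loading with strict validation.

A RunConfig gathers every knob of an end-to-end run — task geometry and
sizes, baseline training, the pruning insult, the three protocol configs,
and the evaluation battery — under one master seed.  Unknown keys are
rejected at load time so silent typos cannot change an experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .task import CANONICAL_CENTERS
from .training import NoiseSchedule
from .treatments import KetamineConfig, NeurosteroidConfig, SsriConfig


def _from_dict(cls, payload: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**payload)


@dataclass(frozen=True)
class DataConfig:
    centers: tuple = CANONICAL_CENTERS
    cluster_sigma: float = 0.8
    n_train: int = 12_000
    n_test_standard: int = 4_000
    n_test_clean: int = 2_000
    input_noise_sigma_standard: float = 0.8


@dataclass(frozen=True)
class BaselineConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 128


@dataclass(frozen=True)
class EvaluationConfig:
    n_repeats: int = 8
    sweep_sigmas: tuple = (0.0, 0.3, 0.5, 1.0, 1.5, 2.0, 2.5)
    relapse_fraction: float = 0.40
    combined_input_sigma: float = 1.0
    combined_internal_sigma: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 42
    hidden_sizes: tuple = (512, 512, 256)
    data: DataConfig = field(default_factory=DataConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    prune_fraction: float = 0.95
    ketamine: KetamineConfig = field(default_factory=KetamineConfig)
    ssri: SsriConfig = field(default_factory=SsriConfig)
    neurosteroid: NeurosteroidConfig = field(default_factory=NeurosteroidConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    output_dir: str = "runs"

    @property
    def layer_sizes(self) -> tuple:
        return (2, *self.hidden_sizes, len(self.data.centers))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown key(s) in run config: {sorted(unknown)}")
        out = {}
        nested = {
            "data": DataConfig, "baseline": BaselineConfig,
            "ketamine": KetamineConfig, "ssri": SsriConfig,
            "neurosteroid": NeurosteroidConfig, "evaluation": EvaluationConfig,
        }
        for key, value in payload.items():
            if key in nested and isinstance(value, dict):
                value = dict(value)
                if key == "ssri" and isinstance(value.get("noise_schedule"), dict):
                    value["noise_schedule"] = _from_dict(
                        NoiseSchedule, value["noise_schedule"], "ssri.noise_schedule")
                out[key] = _from_dict(nested[key], value, key)
            elif key in ("hidden_sizes",):
                out[key] = tuple(value)
            elif key == "data" and not isinstance(value, dict):
                raise ValueError("data block must be a mapping")
            else:
                out[key] = value
        if "data" in out and isinstance(out["data"], DataConfig):
            out["data"] = dataclasses.replace(
                out["data"], centers=tuple(tuple(c) for c in out["data"].centers))
        return cls(**out)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)  # YAML superset also parses JSON
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def checksum(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
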