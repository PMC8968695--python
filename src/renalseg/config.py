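"""Pipeline configuration: one YAML file drives every stage.

The YAML mirrors the dataclass tree (phantom generator, coarse/fine network
and training settings, ROI sizes, split sizes).  ``config_hash`` gives a
stable digest used by the stage manifests for idempotent re-runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .phantoms import PhantomConfig
from .training import CascadeConfig, TrainConfig, desk_profile
from .nn import NetworkConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash",
           "desk_pipeline_config"]


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig
    cascade: CascadeConfig
    n_cases: int = 3
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 2:
            raise ConfigurationError("need at least 2 cases (train + eval)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cascade"]["coarse_net"] = self.cascade.coarse_net.to_dict()
        d["cascade"]["fine_net"] = self.cascade.fine_net.to_dict()
        d["phantom"]["kidney_count_range"] = list(
            self.phantom.kidney_count_range)
        d["phantom"]["tumor_area_range"] = list(self.phantom.tumor_area_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        p = dict(d["phantom"])
        p["kidney_count_range"] = tuple(p["kidney_count_range"])
        p["tumor_area_range"] = tuple(p["tumor_area_range"])
        c = dict(d["cascade"])
        c["coarse_net"] = NetworkConfig.from_dict(c["coarse_net"])
        c["fine_net"] = NetworkConfig.from_dict(c["fine_net"])
        c["coarse_train"] = TrainConfig(**c["coarse_train"])
        c["fine_train"] = TrainConfig(**c["fine_train"])
        return cls(
            phantom=PhantomConfig(**p),
            cascade=CascadeConfig(**c),
            n_cases=d.get("n_cases", 3),
            train_fraction=d.get("train_fraction", 0.8),
            seed=d.get("seed", 0),
        )


def desk_pipeline_config(seed: int = 0, n_cases: int = 4) -> PipelineConfig:
    """The default desk-scale pipeline: small phantoms, small nets."""
    phantom, cascade = desk_profile(seed)
    return PipelineConfig(phantom=phantom, cascade=cascade, n_cases=n_cases,
                          seed=seed)


def save_config(cfg: PipelineConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
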