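"""Pipeline configuration: one YAML document with per-stage blocks.

Every analysis constant has a config home; validation is strict (unknown
keys are rejected before any computation)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class NetworkBlock:
    power: float = 2.0
    min_cluster_size: int = 30
    deep_split: int = 3
    pam_respects_dendro: bool = False
    merge_cut_height: float = 0.25
    kme_threshold: float = 0.8


@dataclass
class PreprocessBlock:
    max_missing_fraction: float = 0.5
    scheme: str = "invitro"  # or "biopsy"
    decimals: int = 6


@dataclass
class SelectionBlock:
    effect_threshold: float = 1.0
    pca_threshold: float = 0.25


@dataclass
class OraBlock:
    p_cut: float = 0.01
    q_cut: float = 0.01


@dataclass
class PpiBlock:
    hub_min_degree: int = 30


@dataclass
class IntegrateBlock:
    high_expression_floor: float = 10.0


@dataclass
class PipelineConfig:
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    network: NetworkBlock = field(default_factory=NetworkBlock)
    selection: SelectionBlock = field(default_factory=SelectionBlock)
    ora: OraBlock = field(default_factory=OraBlock)
    ppi: PpiBlock = field(default_factory=PpiBlock)
    integrate: IntegrateBlock = field(default_factory=IntegrateBlock)

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCKS = {
    "preprocess": PreprocessBlock,
    "network": NetworkBlock,
    "selection": SelectionBlock,
    "ora": OraBlock,
    "ppi": PpiBlock,
    "integrate": IntegrateBlock,
}


class ConfigError(ValueError):
    pass


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    known_top = {"seed", "inputs"} | set(_BLOCKS)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = raw["seed"]
    if "inputs" in raw:
        if not isinstance(raw["inputs"], dict):
            raise ConfigError("inputs must be a mapping")
        kwargs["inputs"] = raw["inputs"]
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"{name} block must be a mapping")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(block) - allowed
        if unknown:
            raise ConfigError(f"unknown keys in {name} block: {sorted(unknown)}")
        kwargs[name] = cls(**block)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})
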