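"""Run configuration: YAML loading with strict key validation and hashing.

Every section maps onto one of the package's config dataclasses; unknown
keys are rejected with the offending name.  The canonical-JSON SHA-256 of
the loaded config is embedded in every artifact a run writes, so outputs
can be traced back to their exact settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .adip import ADIPConfig
from .augment import AugmentConfig
from .encoder import EncoderConfig
from .head import HeadConfig
from .hcmft import MGLAConfig
from .model import ModelConfig
from .preprocess import PreprocessConfig
from .synthio import GeneratorConfig
from .train import ContrastiveConfig, FinetuneConfig


class ConfigError(ValueError):
    pass


@dataclass
class EvaluateConfig:
    scheme: str = "kfold5"
    n_folds: int = 5
    epochs: int = 25
    seeds: tuple[int, ...] = (0, 1, 2)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    verbosity: str = "info"
    simulate: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    hcmft: MGLAConfig = field(default_factory=MGLAConfig)
    adip: ADIPConfig = field(default_factory=ADIPConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    pretrain: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def model_config(self, variant: str = "full",
                     n_layers: int = 3) -> ModelConfig:
        return ModelConfig(encoder=self.encoder, mgla=self.hcmft,
                           adip=self.adip, head=self.head,
                           n_layers=n_layers, variant=variant)


def _build(cls, payload: dict, path: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in known:
            raise ConfigError(f"unknown config key '{path}.{key}'")
        ftype = known[key].type
        default = known[key].default_factory() \
            if known[key].default_factory is not dataclasses.MISSING else None
        if is_dataclass(default):
            kwargs[key] = _build(type(default), value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value) if "tuple" in str(ftype) else value
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{path}': {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; dotted-key overrides win over the file."""
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    for dotted, value in (overrides or {}).items():
        node = payload
        *parents, leaf = dotted.split(".")
        for part in parents:
            node = node.setdefault(part, {})
        node[leaf] = value

    known = {f.name for f in fields(RunConfig)}
    kwargs = {}
    for key, value in payload.items():
        if key not in known:
            raise ConfigError(f"unknown config key '{key}'")
        kwargs[key] = value
    scalars = {k: v for k, v in kwargs.items()
               if k in ("seed", "out_dir", "verbosity")}
    cfg = RunConfig(**scalars)
    for f in fields(RunConfig):
        if f.name in kwargs and f.name not in scalars:
            setattr(cfg, f.name,
                    _build(type(getattr(cfg, f.name)), kwargs[f.name], f.name))
    return cfg


def config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if is_dataclass(o):
            return {f.name: enc(getattr(o, f.name)) for f in fields(o)}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o
    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
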