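"""Pipeline configuration: YAML loading, defaulting, strict validation.

Defaults follow the published hyperparameters (train: 100 epochs, lr 0.001,
epsilon 1e-10, batch 64; optimizer alpha 0.7; augmentation: 90-degree flip,
zoom 0.5-1.0). Unknown keys are rejected and every validation error names
the offending dotted key, e.g. ``train.epochs``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import BACKBONES, TrainConfig
from .edge_planner import SwarmConfig
from .preprocess import AugmentConfig, EnhanceConfig
from .synthetic_data import GeneratorConfig


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorSection:
    n_cobra: int = 30
    n_other: int = 30
    image_size: int = 64


@dataclass
class PreprocessSection:
    side: int = 64
    mu: float = 0.5
    btf_a: float = -0.3293
    btf_b: float = 1.1258


@dataclass
class AugmentSection:
    rotate90: bool = True
    zoom: bool = True
    mirror: bool = False
    zoom_min: float = 0.5
    zoom_max: float = 1.0


@dataclass
class TrainSection:
    epochs: int = 100
    learning_rate: float = 0.001
    epsilon: float = 1e-10
    batch_size: int = 64
    backbone: str = "tiny"
    input_side: int = 64
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1


@dataclass
class EvaluationSection:
    percent_decimals: int = 1


@dataclass
class PlannerSection:
    budget: int = 20
    cost_per_node: float = 0.0
    n_states: int = 3
    method: str = "qpso"
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    alpha: float = 0.7


@dataclass
class LoopSection:
    rounds: int = 3
    cases_per_round: int = 10
    n_edges: int = 2
    retrain_epochs: int = 5
    confirmation_lag: int = 0
    initial_cobra: int = 40
    initial_other: int = 40
    holdout_per_class: int = 20
    initial_epochs: int = 8


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    generator: GeneratorSection = field(default_factory=GeneratorSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    augment: AugmentSection = field(default_factory=AugmentSection)
    train: TrainSection = field(default_factory=TrainSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    planner: PlannerSection = field(default_factory=PlannerSection)
    loop: LoopSection = field(default_factory=LoopSection)

    # -- derived module configs --------------------------------------------

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(image_size=self.generator.image_size)

    def enhance_config(self) -> EnhanceConfig:
        return EnhanceConfig(btf_a=self.preprocess.btf_a,
                             btf_b=self.preprocess.btf_b,
                             mu=self.preprocess.mu)

    def augment_config(self, seed: int) -> AugmentConfig:
        return AugmentConfig(rotate90=self.augment.rotate90,
                             zoom=self.augment.zoom,
                             mirror=self.augment.mirror,
                             zoom_range=(self.augment.zoom_min,
                                         self.augment.zoom_max),
                             seed=seed)

    def train_config(self, seed: int) -> TrainConfig:
        t = self.train
        return TrainConfig(epochs=t.epochs, learning_rate=t.learning_rate,
                           epsilon=t.epsilon, batch_size=t.batch_size,
                           backbone=t.backbone, seed=seed,
                           split=(t.train_frac, t.val_frac, t.test_frac),
                           input_side=t.input_side)

    def swarm_config(self, seed: int) -> SwarmConfig:
        p = self.planner
        return SwarmConfig(swarm_size=p.swarm_size, iterations=p.iterations,
                           inertia=p.inertia, c1=p.c1, c2=p.c2,
                           alpha=p.alpha, seed=seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive an independent per-stage seed from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


_POSITIVE_INT = {
    "generator.n_cobra": (0, None), "generator.n_other": (0, None),
    "generator.image_size": (32, None),
    "preprocess.side": (8, None),
    "train.epochs": (1, None), "train.batch_size": (1, None),
    "train.input_side": (8, None),
    "planner.budget": (1, None), "planner.n_states": (0, None),
    "planner.swarm_size": (2, None), "planner.iterations": (1, None),
    "loop.rounds": (1, None), "loop.cases_per_round": (0, None),
    "loop.n_edges": (1, None), "loop.retrain_epochs": (0, None),
    "loop.confirmation_lag": (0, None), "loop.initial_epochs": (1, None),
}

_UNIT_INTERVAL = {
    "preprocess.mu": (0.0, 1.0, "(0, 1]"),
    "train.learning_rate": (0.0, 1.0, "(0, 1)"),
    "planner.alpha": (0.0, 1.0, "(0, 1]"),
    "planner.inertia": (-1e-12, 1.0, "[0, 1]"),
}


def _get(cfg: PipelineConfig, dotted: str):
    section, key = dotted.split(".")
    return getattr(getattr(cfg, section), key)


def validate(cfg: PipelineConfig) -> PipelineConfig:
    for dotted, (lo, hi) in _POSITIVE_INT.items():
        value = _get(cfg, dotted)
        if not isinstance(value, int) or value < lo or (hi is not None and value > hi):
            raise ConfigError(f"{dotted}: must be an integer >= {lo}, "
                              f"got {value!r}")
    for dotted, (lo, hi, desc) in _UNIT_INTERVAL.items():
        value = _get(cfg, dotted)
        if not (lo < value <= hi):
            raise ConfigError(f"{dotted}: must lie in {desc}, got {value!r}")
    if cfg.train.backbone not in BACKBONES:
        raise ConfigError(f"train.backbone: unknown backbone "
                          f"{cfg.train.backbone!r}; options: {BACKBONES}")
    fracs = (cfg.train.train_frac, cfg.train.val_frac, cfg.train.test_frac)
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError("train.train_frac/val_frac/test_frac: must sum to 1")
    if not (0.0 < cfg.augment.zoom_min <= cfg.augment.zoom_max <= 2.0):
        raise ConfigError("augment.zoom_min/zoom_max: range must lie in (0, 2]")
    if cfg.planner.method not in ("brute", "pso", "qpso"):
        raise ConfigError(f"planner.method: unknown method "
                          f"{cfg.planner.method!r}; options: brute, pso, qpso")
    if cfg.planner.cost_per_node < 0:
        raise ConfigError("planner.cost_per_node: must be >= 0")
    return cfg


def from_dict(raw: dict | None) -> PipelineConfig:
    """Build a validated config from a (possibly partial) mapping."""
    raw = dict(raw or {})
    cfg = PipelineConfig()
    section_types = {f.name: f.type for f in dataclasses.fields(cfg)
                     if dataclasses.is_dataclass(getattr(cfg, f.name))}
    for key in ("seed", "out_dir"):
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    for section, overrides in raw.items():
        if section not in section_types:
            raise ConfigError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        if overrides is None:
            continue
        if not isinstance(overrides, dict):
            raise ConfigError(f"{section}: expected a mapping")
        valid_keys = {f.name for f in dataclasses.fields(target)}
        for key, value in overrides.items():
            if key not in valid_keys:
                raise ConfigError(f"unknown config key {section}.{key}")
            setattr(target, key, value)
    if not isinstance(cfg.seed, int):
        raise ConfigError(f"seed: must be an integer, got {cfg.seed!r}")
    return validate(cfg)


def load_config(path: str | Path) -> PipelineConfig:
    """Load, default, and validate a YAML pipeline config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return from_dict(raw)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
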