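"""Run configuration: one human-readable YAML file drives all stages.

Every field has a documented default; unknown keys are rejected so typos
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantoms import PhantomConfig

__all__ = ["ScheduleConfig", "ModelConfig", "TrainingConfig", "ClassifierConfig",
           "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ScheduleConfig:
    # desk-scale default: T = 1000 convention's betas rescaled 5x for T = 200
    # so the chain still terminates in (near-)pure noise
    T: int = 200
    beta_start: float = 5e-4
    beta_end: float = 0.1
    n_sample_steps: int = 50


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 2
    base_width: int = 16
    emb_dim: int = 512
    emb_mp: float = 10_000.0


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 2e-4
    modality_mix: float = 0.5


@dataclass(frozen=True)
class ClassifierConfig:
    k: int = 5
    hidden: int = 64
    tasks: tuple = ("NC/MCI/AD",)
    views: tuple = (
        ("structural",),
        ("functional",),
        ("structural", "functional_synth_two_way"),
    )


@dataclass(frozen=True)
class PhantomSection:
    image_shape: tuple = (64, 64)
    n_subjects: int = 30
    n_regions: int = 12
    class_effect: dict = field(
        default_factory=lambda: {"NC": 1.0, "MCI": 0.85, "AD": 0.7}
    )
    noise_sd: float = 0.02

    def to_phantom_config(self, seed: int) -> PhantomConfig:
        return PhantomConfig(
            image_shape=tuple(self.image_shape),
            n_subjects=self.n_subjects,
            n_regions=self.n_regions,
            class_effect=dict(self.class_effect),
            noise_sd=self.noise_sd,
            seed=seed,
        )


@dataclass(frozen=True)
class RunConfig:
    phantoms: PhantomSection = field(default_factory=PhantomSection)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    out_dir: str = "runs/demo"


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {unknown}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = {
            "phantoms": PhantomSection,
            "schedule": ScheduleConfig,
            "model": ModelConfig,
            "training": TrainingConfig,
            "classifier": ClassifierConfig,
        }.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}" if path else name)
        elif name in ("image_shape", "tasks"):
            kwargs[name] = tuple(value)
        elif name == "views":
            kwargs[name] = tuple(tuple(v) for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return _build(RunConfig, data, "")


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=False)
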