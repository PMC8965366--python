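"""Run configuration: one serializable object tying cohort, folds, network
specs, stage schedule and evaluation together, with two shipped profiles.

* ``full_scale_profile`` — the full-scale geometry (128^3 volumes, 64..1024
  channel widths, 64^3 patches at stride 32).  Faithful to the method's
  stated scale; intended as a reference, not for CPU execution.
* ``desk_profile`` — the standard desk-scale benchmark every test and the
  acceptance script run on: 16^3 volumes, 1/16 channel widths, depth-2
  generator, whole-volume patches, 8 paired + 4 unpaired subjects per
  class, 4 stratified folds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .networks import DiscriminatorSpec, FusionSpec, GeneratorSpec
from .synthetic import SyntheticConfig
from .training import Stage1Config, Stage2Config, Stage3Config, StageConfig

__all__ = ["RunConfig", "desk_profile", "full_scale_profile", "load_config", "save_config"]


@dataclass
class RunConfig:
    cohort_dir: str | None = None
    output_dir: str = "runs/run0"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: StageConfig = field(default_factory=StageConfig)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    protocol: str = "incomplete"
    folds: int = 10
    validation_fold: int = 0
    patch_size: int = 64
    patch_stride: int = 32
    seed: int = 0
    deterministic: bool = True

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = _from_dict(asdict(self))
        cfg.seed = seed
        cfg.synthetic.seed = seed
        cfg.stages.seed = seed
        return cfg


def desk_profile(seed: int = 0) -> RunConfig:
    """Desk-scale study conditions (see docs/methods.md for rationale)."""
    return RunConfig(
        synthetic=SyntheticConfig(
            volume_size=16,
            n_paired_per_class=8,
            n_unpaired_per_class=4,
            smoothness=2.0,
            effect_size=0.4,
            noise_sd=0.05,
            seed=seed,
        ),
        stages=StageConfig(
            stage1=Stage1Config(lr=5e-3, batch=8, l2=1e-3, epochs=30),
            stage2=Stage2Config(
                lr=5e-3, d_lr=2.5e-4, d_steps_per_g_step=5,
                weights=LossWeights(), epochs=40,
            ),
            stage3=Stage3Config(lr=1e-3, batch=8, l2=1e-3, epochs=20),
            cycles=1,
            seed=seed,
        ),
        generator=GeneratorSpec(encoder_channels=[4, 8], decoder_channels=[8, 1]),
        discriminator=DiscriminatorSpec(channels=[2, 4, 8], input_edge=16),
        fusion=FusionSpec(branch_blocks=2, trunk_blocks=1, base_channels=4, input_edge=16),
        folds=4,
        patch_size=16,
        patch_stride=8,
        seed=seed,
    )


def full_scale_profile(seed: int = 0) -> RunConfig:
    return RunConfig(
        synthetic=SyntheticConfig(
            volume_size=128,
            n_paired_per_class=128,
            n_unpaired_per_class=52,
            missing_label_policy="imbalanced",
            seed=seed,
        ),
        stages=StageConfig(cycles=3, seed=seed),
        generator=GeneratorSpec(),
        discriminator=DiscriminatorSpec(input_edge=64),
        fusion=FusionSpec(branch_blocks=3, trunk_blocks=2, base_channels=8, input_edge=128),
        folds=10,
        patch_size=64,
        patch_stride=32,
        seed=seed,
    )


def _from_dict(data: dict) -> RunConfig:
    def build(cls, sub):
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in sub.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
            ftype = fields[key].type
            nested = {
                "synthetic": SyntheticConfig,
                "stages": StageConfig,
                "generator": GeneratorSpec,
                "discriminator": DiscriminatorSpec,
                "fusion": FusionSpec,
                "stage1": Stage1Config,
                "stage2": Stage2Config,
                "stage3": Stage3Config,
                "weights": LossWeights,
            }
            if key in nested and isinstance(value, dict):
                kwargs[key] = build(nested[key], value)
            elif key == "lesion_regions" and value is not None:
                kwargs[key] = [
                    (tuple(center), int(radius)) for center, radius in value
                ]
            else:
                kwargs[key] = value
        return cls(**kwargs)

    return build(RunConfig, data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    return path


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data.update(overrides)
    return _from_dict(data)
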