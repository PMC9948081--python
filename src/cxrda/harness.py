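"""Run configuration, provenance and manifest utilities.

A single YAML file with per-module sections (``generate``, ``preprocess``,
``architecture``, ``training``, ``evaluation``, ``paths``) is the source of
truth for an experiment.  Every sub-config is validated before any compute
starts, and the resolved configuration (with the effective seed and package
version) is persisted verbatim next to the outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .architectures import EncoderConfig
from .manifest import DatasetManifest, read_manifest, write_manifest  # noqa: F401 (re-export)
from .objectives import LossWeights
from .phantom import DomainShift
from .preprocess import PreprocessConfig
from .splits import split_stratified  # noqa: F401 (re-export)
from .training import TrainingConfig


class ConfigError(ValueError):
    pass


def _dataclass_from(cls, section: dict, context: str):
    if section is None:
        section = {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    coerced = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in coerced[f.name]
            )
    return cls(**coerced)


@dataclass
class RunConfig:
    """Validated experiment configuration."""

    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, seed_override: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)
        cfg = cls(seed=seed, raw=raw)
        cfg.validate()
        return cfg

    # -- section builders ---------------------------------------------------
    def generation_specs(self) -> dict[str, dict]:
        gen = self.raw.get("generate", {})
        if not gen:
            raise ConfigError("config has no 'generate' section")
        specs = {}
        for name, sec in gen.items():
            sec = dict(sec)
            shift = _dataclass_from(DomainShift, sec.pop("shift", {}), f"generate.{name}.shift")
            shift.validate()
            specs[name] = {"shift": shift, **sec}
        return specs

    def preprocess_config(self) -> PreprocessConfig:
        cfg = _dataclass_from(PreprocessConfig, self.raw.get("preprocess", {}), "preprocess")
        cfg.validate()
        return cfg

    def encoder_config(self) -> EncoderConfig:
        cfg = _dataclass_from(EncoderConfig, self.raw.get("architecture", {}), "architecture")
        cfg.validate()
        return cfg

    def training_config(self, mode: str | None = None) -> TrainingConfig:
        sec = dict(self.raw.get("training", {}))
        if "loss_weights" in sec:
            sec["loss_weights"] = _dataclass_from(
                LossWeights, sec["loss_weights"], "training.loss_weights")
        if mode is not None:
            sec["mode"] = mode
        sec["seed"] = self.seed
        cfg = _dataclass_from(TrainingConfig, sec, "training")
        cfg.validate()
        return cfg

    def evaluation_modes(self) -> tuple[str, ...]:
        modes = tuple(self.raw.get("evaluation", {}).get("modes",
                                                         ("t2t", "s2t", "drda", "rdrda")))
        allowed = {"t2t", "s2t", "drda", "rdrda"}
        bad = set(modes) - allowed
        if bad:
            raise ConfigError(f"unknown evaluation modes: {sorted(bad)}")
        return modes

    def path(self, key: str) -> Path:
        paths = self.raw.get("paths", {})
        if key not in paths:
            raise ConfigError(f"config paths section lacks {key!r}")
        return Path(paths[key])

    def validate(self) -> None:
        """Build every present section once so bad configs fail up front."""
        if "generate" in self.raw:
            self.generation_specs()
        if "preprocess" in self.raw:
            self.preprocess_config()
        if "architecture" in self.raw:
            self.encoder_config()
        if "training" in self.raw:
            self.training_config()
        if "evaluation" in self.raw:
            self.evaluation_modes()

    def persist(self, out_dir: str | Path) -> None:
        """Write the resolved config + seed + package version alongside outputs."""
        from . import __version__

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        resolved = dict(self.raw)
        resolved["seed"] = self.seed
        resolved["package_version"] = __version__
        (out_dir / "run_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=False))
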