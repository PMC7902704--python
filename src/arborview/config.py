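"""Run configuration: YAML file -> validated dataclass sections.

Unknown keys are rejected (all violations reported at once), and every run
writes a resolved-config snapshot next to its artifacts so any output can be
regenerated from the directory alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .augmentation import AugmentConfig
from .cnn_classifier import CNNConfig
from .projection import RenderConfig
from .synthetic_trees import BROADLEAF, CONIFER, INTERMEDIATE, ArchetypeParams

__all__ = ["RunConfig", "load_config", "ConfigError"]

ARCHETYPE_PRESETS = {
    "conifer": CONIFER,
    "broadleaf": BROADLEAF,
    "intermediate": INTERMEDIATE,
}


class ConfigError(ValueError):
    """Raised with an exhaustive list of configuration problems."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One synthetic species: an archetype preset plus optional overrides."""

    archetype: str = "conifer"
    n_trees: int = 10
    overrides: dict[str, Any] = field(default_factory=dict)

    def params(self) -> ArchetypeParams:
        if self.archetype not in ARCHETYPE_PRESETS:
            raise ConfigError(
                f"unknown archetype {self.archetype!r}; "
                f"choose from {sorted(ARCHETYPE_PRESETS)}"
            )
        base = ARCHETYPE_PRESETS[self.archetype]
        if not self.overrides:
            return base
        return dataclasses.replace(
            base,
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in self.overrides.items()
            },
        )


@dataclass(frozen=True)
class SimulateSection:
    species: dict[str, SpeciesSpec] = field(
        default_factory=lambda: {
            "conifer": SpeciesSpec("conifer", 10),
            "broadleaf": SpeciesSpec("broadleaf", 10),
        }
    )


@dataclass(frozen=True)
class SplitSection:
    test_fraction: float = 0.2
    per_species_test_counts: dict[str, int] | None = None


@dataclass(frozen=True)
class EvaluateSection:
    per_tree: bool = False


@dataclass(frozen=True)
class PointnetSection:
    n_points: int = 2048
    n_repeats: int = 10
    fraction: float = 0.3


@dataclass(frozen=True)
class RunConfig:
    """All pipeline sections plus the global seed and subsample size."""

    seed: int = 0
    subsample_n: int = 6000
    simulate: SimulateSection = field(default_factory=SimulateSection)
    render: RenderConfig = field(default_factory=RenderConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    split: SplitSection = field(default_factory=SplitSection)
    model: CNNConfig = field(default_factory=CNNConfig)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)
    pointnet_prep: PointnetSection = field(default_factory=PointnetSection)

    def to_snapshot(self, path: str | Path) -> None:
        """Write the fully resolved configuration as JSON."""
        Path(path).write_text(json.dumps(_as_jsonable(self), indent=2))


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _build_dataclass(cls, data: Mapping[str, Any], path: str, errors: list[str]):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    for key in sorted(unknown):
        errors.append(f"{path}.{key}: unknown key (valid: {sorted(names)})")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return cls()


def _build_simulate(data: Mapping[str, Any], errors: list[str]) -> SimulateSection:
    unknown = set(data) - {"species"}
    for key in sorted(unknown):
        errors.append(f"simulate.{key}: unknown key (valid: ['species'])")
    if "species" not in data:
        return SimulateSection()
    species = {}
    for name, spec in data["species"].items():
        spec = dict(spec)
        archetype = spec.pop("archetype", "conifer")
        n_trees = spec.pop("n_trees", 10)
        valid = {f.name for f in fields(ArchetypeParams)}
        bad = set(spec) - valid
        for key in sorted(bad):
            errors.append(f"simulate.species.{name}.{key}: unknown key")
        species[name] = SpeciesSpec(
            archetype=archetype,
            n_trees=int(n_trees),
            overrides={k: v for k, v in spec.items() if k in valid},
        )
    return SimulateSection(species=species)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration, validating every section strictly."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded

    errors: list[str] = []
    sections = {
        "render": RenderConfig,
        "augment": AugmentConfig,
        "split": SplitSection,
        "model": CNNConfig,
        "evaluate": EvaluateSection,
        "pointnet_prep": PointnetSection,
    }
    top_valid = set(sections) | {"simulate", "seed", "subsample_n"}
    for key in sorted(set(data) - top_valid):
        errors.append(f"{key}: unknown top-level key (valid: {sorted(top_valid)})")

    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        if name in data:
            kwargs[name] = _build_dataclass(cls, data[name] or {}, name, errors)
    if "simulate" in data:
        kwargs["simulate"] = _build_simulate(data["simulate"] or {}, errors)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "subsample_n" in data:
        kwargs["subsample_n"] = int(data["subsample_n"])
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    cfg = RunConfig(**kwargs)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg
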