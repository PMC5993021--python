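"""Run configuration: validated parameters for the full pipeline.

The config file is plain YAML whose keys mirror :class:`RunConfig`;
validation happens before any computation and every error names the
offending key.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .populations import PopulationDef
from .segment import NucleiParams


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


@dataclasses.dataclass(frozen=True)
class PreprocessParams:
    rolling_ball_radius: int = 50
    enhance_contrast: float | None = None  # saturated fraction; None = off
    illumination_smoothing_px: float = 64.0


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides the images themselves."""

    preprocess: PreprocessParams = PreprocessParams()
    nuclei: NucleiParams = NucleiParams()
    populations: tuple[PopulationDef, ...] = ()
    min_overlap_fraction: float = 0.5
    contact_radius_px: float | None = None
    secondary_regularization: float = 0.0
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap_fraction <= 1.0:
            raise ConfigError("key 'min_overlap_fraction' must be in (0, 1]")
        if self.secondary_regularization < 0:
            raise ConfigError("key 'secondary_regularization' must be nonnegative")
        names = [p.name for p in self.populations]
        if len(names) != len(set(names)):
            raise ConfigError("key 'populations' contains duplicate names")

    def validate_channels(self, available: list[str]) -> None:
        for pop in self.populations:
            if pop.stain_channel not in available:
                raise ConfigError(
                    f"population {pop.name!r} references channel "
                    f"{pop.stain_channel!r}, not among available channels "
                    f"{sorted(available)}"
                )


def _build(cls, section: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown config key '{context}.{sorted(unknown)[0]}'")
    try:
        return cls(**section)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in config section '{context}': {exc}") from exc


_TOP_KEYS = {
    "preprocess",
    "nuclei",
    "populations",
    "min_overlap_fraction",
    "contact_radius_px",
    "secondary_regularization",
    "output_dir",
    "seed",
    "log_level",
}


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key '{sorted(unknown)[0]}'")
    pre = _build(PreprocessParams, dict(data.get("preprocess") or {}), "preprocess")
    nuc = _build(NucleiParams, dict(data.get("nuclei") or {}), "nuclei")
    pops_raw = data.get("populations") or []
    if not isinstance(pops_raw, list):
        raise ConfigError("key 'populations' must be a list")
    pops = []
    for i, entry in enumerate(pops_raw):
        if not isinstance(entry, dict):
            raise ConfigError(f"key 'populations[{i}]' must be a mapping")
        pops.append(_build(PopulationDef, dict(entry), f"populations[{i}]"))
    scalars = {
        k: data[k]
        for k in (
            "min_overlap_fraction",
            "contact_radius_px",
            "secondary_regularization",
            "output_dir",
            "seed",
            "log_level",
        )
        if k in data
    }
    for key in ("min_overlap_fraction", "secondary_regularization"):
        if key in scalars and not isinstance(scalars[key], (int, float)):
            raise ConfigError(f"key '{key}' must be a number")
    if "seed" in scalars and not isinstance(scalars["seed"], int):
        raise ConfigError("key 'seed' must be an integer")
    try:
        return RunConfig(preprocess=pre, nuclei=nuc, populations=tuple(pops), **scalars)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run-configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
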