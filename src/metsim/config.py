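"""YAML run configuration with strict schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .adapt import AdaptConfig
from .model import DIET_HFD, DIET_HFDC, DIET_LFD, DietInput, ObservationMap

__all__ = ["RunConfig", "load_config", "ConfigError", "DEFAULT_DIETS"]

DEFAULT_DIETS = {
    "LFD": DIET_LFD,
    "HFD": DIET_HFD,
    "MetS_non-DLP": DIET_HFDC,
    "MetS_DLP": DIET_HFDC,
}


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class CalibrationSettings:
    n_starts: int = 500
    wsse_threshold: float = 100.0


@dataclass
class RunConfig:
    """Top-level run configuration.

    ``diets`` maps group names to diet compositions (energy density in
    kcal/g, energy fractions, cholesterol w/w fraction, intake g/day).
    """

    seed: int = 0
    output_dir: str = "."
    diets: dict[str, DietInput] = field(
        default_factory=lambda: dict(DEFAULT_DIETS))
    observation: ObservationMap = field(default_factory=ObservationMap)
    adapt: AdaptConfig = field(default_factory=AdaptConfig)
    calibration: CalibrationSettings = field(
        default_factory=CalibrationSettings)

    def diet_for(self, group: str) -> DietInput:
        try:
            return self.diets[group]
        except KeyError:
            raise ConfigError(
                f"no diet configured for group {group!r}; "
                f"have {sorted(self.diets)}") from None


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are
    rejected with the offending section named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    if "diets" in raw:
        diets = {}
        for group, section in raw["diets"].items():
            diets[group] = _build(DietInput, section, f"diets.{group}")
        kwargs["diets"] = diets
    if "observation" in raw:
        kwargs["observation"] = _build(ObservationMap, raw["observation"],
                                       "observation")
    if "adapt" in raw:
        section = dict(raw["adapt"])
        if "free_parameters" in section and \
                section["free_parameters"] is not None:
            section["free_parameters"] = tuple(section["free_parameters"])
        kwargs["adapt"] = _build(AdaptConfig, section, "adapt")
    if "calibration" in raw:
        kwargs["calibration"] = _build(CalibrationSettings,
                                       raw["calibration"], "calibration")
    return RunConfig(**kwargs)
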