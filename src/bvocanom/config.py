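"""Run configuration: schema-validated coefficients and paths.

One YAML document carries every coefficient the pipeline needs (response
parameters, biomass regressions, class weights, error margins) plus run
settings (reference year, smoothing windows, mixing radius, seed).
Validation errors name the offending field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Mapping, Optional

import yaml

from .attribution import DEFAULT_REFERENCE_YEAR, ErrorBudget
from .drivers import BiomassModel, ResponseParams

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration failed validation; message names the field."""


@dataclass(frozen=True)
class RunConfig:
    params: ResponseParams = field(default_factory=ResponseParams)
    biomass_model: BiomassModel = field(default_factory=BiomassModel)
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"forest": 1 / 3, "agriculture": 0.5, "grassland": 1 / 6}
    )
    error_budget: ErrorBudget = field(default_factory=ErrorBudget)
    reference_year: int = DEFAULT_REFERENCE_YEAR
    smoothing_windows: tuple[int, ...] = (4, 7)
    radius_km: float = 15.0
    seed: int = 0
    driver_paths: Mapping[str, str] = field(default_factory=dict)
    scenario_path: Optional[str] = None
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(
                f"schema_version: expected {CONFIG_SCHEMA_VERSION}, got {self.schema_version}"
            )
        for cls, w in self.class_weights.items():
            if w < 0:
                raise ConfigError(f"class_weights.{cls}: must be >= 0, got {w}")
        if self.radius_km < 0:
            raise ConfigError(f"radius_km: must be >= 0, got {self.radius_km}")
        for w in self.smoothing_windows:
            if w < 1:
                raise ConfigError(f"smoothing_windows: window must be >= 1, got {w}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        d["biomass_model"] = {
            "intercepts": dict(self.biomass_model.intercepts),
            "slopes": dict(self.biomass_model.slopes),
            "ndvi_range": list(self.biomass_model.ndvi_range),
        }
        d["error_budget"] = {"margins": dict(self.error_budget.margins),
                             "method": self.error_budget.method}
        d["class_weights"] = dict(self.class_weights)
        d["smoothing_windows"] = list(self.smoothing_windows)
        d["driver_paths"] = dict(self.driver_paths)
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _build(section: dict, cls, name: str):
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def config_from_dict(doc: dict) -> RunConfig:
    doc = dict(doc or {})
    kwargs: dict = {}
    if "params" in doc:
        kwargs["params"] = _build(doc.pop("params"), ResponseParams, "params")
    if "biomass_model" in doc:
        section = dict(doc.pop("biomass_model"))
        if "ndvi_range" in section:
            section["ndvi_range"] = tuple(section["ndvi_range"])
        kwargs["biomass_model"] = _build(section, BiomassModel, "biomass_model")
    if "error_budget" in doc:
        kwargs["error_budget"] = _build(doc.pop("error_budget"), ErrorBudget, "error_budget")
    if "smoothing_windows" in doc:
        kwargs["smoothing_windows"] = tuple(doc.pop("smoothing_windows"))
    known = {"class_weights", "reference_year", "radius_km", "seed",
             "driver_paths", "scenario_path", "schema_version"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    kwargs.update(doc)
    try:
        return RunConfig(**kwargs)
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_worked_examples() -> dict:
    """Packaged fixture of in-text worked-example inputs (printed driver
    contributions, the heath-fire event, seasonal numbers)."""
    text = resources.files("bvocanom.data").joinpath("worked_examples.yaml").read_text()
    return yaml.safe_load(text)
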