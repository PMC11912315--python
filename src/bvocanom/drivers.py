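"""Per-driver emission response functions.

Each driver of the long-term emission anomaly gets its own contribution
function: vegetation biomass via NDVI regression, an exponential temperature
activity factor, a power-law CO2 inhibition of isoprene, a linear
soil-moisture term, and the burnt-biomass calculus for discrete wildfire
events.  All contributions are dimensionless fractions; percent appears only
at I/O boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DRIVER_KINDS = ("NDVI", "temperature", "CO2", "soil_moisture")

#: default physical units per driver kind
DEFAULT_UNITS = {
    "NDVI": "index",
    "temperature": "degC",
    "CO2": "ratio",
    "soil_moisture": "m3/m3",
}


@dataclass(frozen=True)
class FactorSeries:
    """A single driver's time-stamped values.

    Parameters
    ----------
    timestamps
        Decimal years, strictly increasing.
    values
        Driver values, same length as ``timestamps``; must be finite.
    kind
        One of :data:`DRIVER_KINDS`.
    units
        Free-text unit label.
    """

    timestamps: np.ndarray
    values: np.ndarray
    kind: str
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if self.kind not in DRIVER_KINDS:
            raise ValueError(f"unknown driver kind {self.kind!r}; expected one of {DRIVER_KINDS}")
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("timestamps and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty series")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError("non-finite timestamps or values")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.kind == "NDVI" and (v.min() < -1.0 or v.max() > 1.0):
            raise ValueError("NDVI values must lie in [-1, 1]")
        if self.kind == "soil_moisture" and v.min() < 0:
            raise ValueError("soil moisture must be non-negative")
        if not self.units:
            object.__setattr__(self, "units", DEFAULT_UNITS[self.kind])

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def cadence(self) -> int:
        """Samples per year, inferred from median spacing (1 for annual)."""
        if len(self) < 2:
            return 1
        return max(1, int(round(1.0 / float(np.median(np.diff(self.timestamps))))))

    def annual(self) -> "FactorSeries":
        """Collapse to yearly means on integer-year timestamps."""
        years = np.floor(self.timestamps).astype(int)
        uniq = np.unique(years)
        means = np.array([self.values[years == y].mean() for y in uniq], dtype=float)
        return FactorSeries(uniq.astype(float), means, self.kind, self.units)

    def at_year(self, year: int) -> float:
        """Yearly-mean value for a calendar year."""
        mask = np.floor(self.timestamps).astype(int) == int(year)
        if not mask.any():
            raise ValueError(f"{self.kind} series does not cover year {year}")
        return float(self.values[mask].mean())

    def year_span(self) -> tuple[int, int]:
        years = np.floor(self.timestamps).astype(int)
        return int(years.min()), int(years.max())


@dataclass(frozen=True)
class BiomassModel:
    """Linear per-class NDVI -> biomass-density regressions (t/ha).

    Coefficients are configuration inputs (fitted elsewhere); the model is
    only evaluated inside ``ndvi_range``.  Default coefficients are chosen so
    that forest biomass at peak NDVI is about 293 t/ha, the density used for
    temperate forest in the wildfire calculus.
    """

    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"forest": 23.0, "agriculture": 5.0, "grassland": 2.0}
    )
    slopes: Mapping[str, float] = field(
        default_factory=lambda: {"forest": 300.0, "agriculture": 160.0, "grassland": 60.0}
    )
    ndvi_range: tuple[float, float] = (0.0, 0.9)

    def __post_init__(self) -> None:
        if set(self.intercepts) != set(self.slopes):
            raise ValueError("intercepts and slopes must cover the same classes")
        lo, hi = self.ndvi_range
        if not lo < hi:
            raise ValueError("ndvi_range must be (low, high) with low < high")
        for cls, s in self.slopes.items():
            if s <= 0:
                raise ValueError(f"slope for vegetated class {cls!r} must be positive")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.intercepts)


@dataclass(frozen=True)
class ResponseParams:
    """Scalar response coefficients shared across the pipeline.

    beta_t
        Exponential temperature coefficient (per degC).
    beta_co2
        CO2 sensitivity of isoprene (dimensionless).
    isoprene_share
        Isoprene fraction of total emissions.
    dry_scaling
        Green -> dry biomass conversion for burnt material.
    background_rate
        Typical temperate-forest emission rate, kg/ha/day.
    """

    beta_t: float = 0.1
    beta_co2: float = 0.33
    isoprene_share: float = 0.5
    dry_scaling: float = 0.5
    background_rate: float = 0.26

    def __post_init__(self) -> None:
        for name in ("beta_t", "beta_co2", "isoprene_share", "dry_scaling", "background_rate"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        for name in ("isoprene_share", "dry_scaling"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class WildfireEvent:
    """A single burnt-area event.

    ``emission_factors`` is a sequence of ``(value g/kg dry, weight)`` pairs
    whose weights sum to 1.
    """

    area: float  # ha
    forest_fraction: float = 0.9
    green_biomass_density: float = 293.0  # t/ha
    emission_factors: Sequence[tuple[float, float]] = ((0.5, 0.5), (0.2, 0.5))
    duration: Optional[float] = None  # days
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if not 0 <= self.forest_fraction <= 1:
            raise ValueError("forest_fraction must lie in [0, 1]")
        if self.emission_factors:
            w = sum(wt for _, wt in self.emission_factors)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"emission-factor weights must sum to 1, got {w}")


@dataclass(frozen=True)
class ContributionSet:
    """Per-driver fractional contributions to the emission anomaly."""

    biomass_parts: Mapping[str, float]
    temperature: float
    co2: float
    soil_moisture: float
    margins: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("temperature", "co2", "soil_moisture"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite contribution: {name}")
        for cls, part in self.biomass_parts.items():
            if not math.isfinite(part):
                raise ValueError(f"non-finite biomass part for class {cls!r}")
        if self.margins is not None:
            for k, m in self.margins.items():
                if m < 0:
                    raise ValueError(f"margin for {k!r} must be >= 0")

    @property
    def biomass(self) -> float:
        """Total biomass contribution (sum of per-class parts)."""
        return float(sum(self.biomass_parts.values()))

    @property
    def environmental(self) -> float:
        """Sum of the non-biomass contributions."""
        return self.temperature + self.co2 + self.soil_moisture


# ---------------------------------------------------------------------------
# biomass

def ndvi_to_biomass(ndvi: float, pft_class: str, model: BiomassModel) -> float:
    """Biomass density (t/ha) from NDVI through the class regression.

    Negative predictions are clamped to 0 with a logged warning.
    """
    if pft_class not in model.intercepts:
        raise ValueError(f"unknown class {pft_class!r}; model covers {model.classes}")
    lo, hi = model.ndvi_range
    ndvi_arr = np.asarray(ndvi, dtype=float)
    if np.any(ndvi_arr < lo) or np.any(ndvi_arr > hi):
        raise ValueError(f"NDVI outside model's valid range [{lo}, {hi}]")
    out = model.intercepts[pft_class] + model.slopes[pft_class] * ndvi_arr
    if np.any(out < 0):
        logger.warning("negative biomass prediction clamped to 0 for class %s", pft_class)
        out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(ndvi) or ndvi_arr.ndim == 0 else out


def biomass_contribution(
    per_class_relative_change: Mapping[str, float],
    per_class_weight: Mapping[str, float],
) -> tuple[float, dict[str, float]]:
    """Area-weighted biomass contribution.

    Returns ``(total, parts)`` with ``parts[c] = weight[c] * change[c]``.
    """
    if set(per_class_relative_change) != set(per_class_weight):
        raise ValueError(
            "class sets differ: changes cover "
            f"{sorted(per_class_relative_change)}, weights cover {sorted(per_class_weight)}"
        )
    for cls, w in per_class_weight.items():
        if w < 0:
            raise ValueError(f"weight for class {cls!r} must be >= 0")
    parts = {c: per_class_weight[c] * per_class_relative_change[c] for c in per_class_relative_change}
    return float(sum(parts.values())), parts


# ---------------------------------------------------------------------------
# environmental activities

def temperature_activity(delta_t: float, beta: float = 0.1) -> float:
    """Fractional emission change from a temperature offset: exp(beta*dT) - 1."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not np.all(np.isfinite(np.asarray(delta_t, dtype=float))):
        raise ValueError("non-finite temperature offset")
    return np.exp(beta * np.asarray(delta_t, dtype=float)) - 1.0 if np.ndim(delta_t) else float(math.exp(beta * delta_t) - 1.0)


def co2_activity(concentration_ratio: float, beta_co2: float = 0.33) -> float:
    """Isoprene fractional change from a CO2 concentration ratio C/C0.

    Power-law inhibition ``(C/C0)**(-beta) - 1``: decreasing in the ratio and
    zero at the reference concentration.
    """
    ratio = np.asarray(concentration_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("concentration ratio must be > 0")
    if beta_co2 < 0:
        raise ValueError("beta_co2 must be >= 0")
    out = ratio ** (-beta_co2) - 1.0
    return float(out) if out.ndim == 0 else out


def isoprene_to_total(isoprene_change: float, isoprene_share: float = 0.5) -> float:
    """Scale an isoprene-only change to total emissions by the isoprene share."""
    if not 0 <= isoprene_share <= 1:
        raise ValueError("isoprene_share must lie in [0, 1]")
    return isoprene_change * isoprene_share


def soil_moisture_contribution(sm: float, sm0: float) -> float:
    """Linear soil-moisture term: relative anomaly (sm - sm0)/sm0."""
    if sm0 <= 0:
        raise ValueError("reference soil moisture must be > 0")
    out = (np.asarray(sm, dtype=float) - sm0) / sm0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# wildfire calculus

def wildfire_dry_biomass(event: WildfireEvent, dry_scaling: float = 0.5) -> float:
    """Dry burnt biomass (t): area * forest fraction * green density * scaling."""
    if not 0 <= dry_scaling <= 1:
        raise ValueError("dry_scaling must lie in [0, 1]")
    return event.area * event.forest_fraction * event.green_biomass_density * dry_scaling


def wildfire_emission(dry_mass: float, emission_factors: Sequence[tuple[float, float]]) -> float:
    """Emitted mass (t) from dry burnt biomass and weighted emission factors (g/kg)."""
    if not emission_factors:
        raise ValueError("emission factor list must not be empty")
    w = sum(wt for _, wt in emission_factors)
    if abs(w - 1.0) > 1e-9:
        raise ValueError(f"emission-factor weights must sum to 1, got {w}")
    mean_ef = sum(ef * wt for ef, wt in emission_factors)  # g/kg == kg/t * 1e-3
    return dry_mass * mean_ef * 1e-3


def wildfire_rate(
    emitted: float, area: float, duration: float, background_rate: float = 0.26
) -> tuple[float, float]:
    """Per-area emission rate (kg/ha/day) and its ratio to the background rate.

    ``emitted`` is in tonnes; the rate is ``emitted * 1e3 / (area * duration)``.
    """
    if area <= 0 or duration <= 0:
        raise ValueError("area and duration must be > 0")
    rate = emitted * 1e3 / (area * duration)
    ratio = rate / background_rate if background_rate > 0 else math.inf if rate > 0 else 0.0
    return rate, ratio


def wildfire_event_emission(event: WildfireEvent, params: ResponseParams) -> float:
    """Convenience: emitted mass (t) for one event under the given parameters."""
    dry = wildfire_dry_biomass(event, params.dry_scaling)
    return wildfire_emission(dry, event.emission_factors)
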