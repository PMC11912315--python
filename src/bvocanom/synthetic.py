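"""Synthetic driver generators with known ground truth.

Every pipeline stage is testable without downloads: driver time series are a
linear trend plus a single seasonal cosine harmonic (amplitude itself may
trend) plus Gaussian noise; vegetation maps are quota-assigned categorical
grids; wildfire events are Poisson counts with lognormal burnt areas.

One seed spawns independent substreams per purpose (series noise, grid,
gridded noise, events) so adding a generator never perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .drivers import DRIVER_KINDS, FactorSeries, WildfireEvent
from .spatial import PFT_CLASSES, GriddedSeries, PFTGrid

logger = logging.getLogger(__name__)

#: seasonal cosine peaks at this fraction of the year (mid-July)
MIDSUMMER_FRACTION = 0.54

# substream purposes
_SERIES, _GRID, _GRIDDED, _EVENTS = range(4)


def _rng(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(purpose,)))


@dataclass(frozen=True)
class GenSpec:
    """Recipe for one synthetic driver series."""

    start_year: int
    end_year: int
    cadence: int = 1  # samples per year
    baseline: float = 0.0
    trend: float = 0.0  # units per year
    seasonal_amplitude: float = 0.0
    seasonal_amplitude_trend: float = 0.0  # units per year
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must be after start_year")
        if self.cadence < 1:
            raise ValueError("cadence must be >= 1 sample per year")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")

    def timestamps(self) -> np.ndarray:
        n = (self.end_year - self.start_year + 1) * self.cadence
        return self.start_year + np.arange(n) / self.cadence

    def deterministic_curve(self, t: np.ndarray | None = None) -> np.ndarray:
        """Noise-free model curve on the spec's (or a given) timeline."""
        if t is None:
            t = self.timestamps()
        elapsed = t - self.start_year
        amp = self.seasonal_amplitude + self.seasonal_amplitude_trend * elapsed
        phase = (t % 1.0) - MIDSUMMER_FRACTION
        return self.baseline + self.trend * elapsed + amp * np.cos(2 * np.pi * phase)


@dataclass(frozen=True)
class GridSpec:
    """Recipe for a categorical vegetation grid."""

    n_rows: int
    n_cols: int
    class_fractions: Mapping[str, float]
    pixel_size: float = 500.0  # metres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one pixel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        total = 0.0
        for cls, f in self.class_fractions.items():
            if cls not in PFT_CLASSES:
                raise ValueError(f"unknown class {cls!r}; expected one of {PFT_CLASSES}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {cls!r} must lie in [0, 1]")
            total += f
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")


def generate_driver_series(spec: GenSpec, kind: str) -> FactorSeries:
    """One driver series from its recipe; reproducible for a fixed seed.

    NDVI is clipped to [-1, 1] after noise; clipping events are logged.
    """
    if kind not in DRIVER_KINDS:
        raise ValueError(f"unknown driver kind {kind!r}; expected one of {DRIVER_KINDS}")
    t = spec.timestamps()
    values = spec.deterministic_curve(t)
    if spec.noise_sd > 0:
        values = values + _rng(spec.seed, _SERIES).normal(0.0, spec.noise_sd, size=t.size)
    if kind == "NDVI":
        n_clip = int(np.sum((values < -1) | (values > 1)))
        if n_clip:
            logger.info("clipped %d NDVI samples to [-1, 1]", n_clip)
        values = np.clip(values, -1.0, 1.0)
    if kind == "soil_moisture":
        values = np.maximum(values, 0.0)
    return FactorSeries(t, values, kind)


def generate_pft_grid(spec: GridSpec) -> PFTGrid:
    """Quota assignment over a sorted random field.

    Pixel counts per class are the largest-remainder quotas of the requested
    fractions, so realized fractions match to within one pixel of rounding.
    """
    n = spec.n_rows * spec.n_cols
    targets = {c: f * n for c, f in spec.class_fractions.items()}
    counts = {c: int(np.floor(x)) for c, x in targets.items()}
    short = n - sum(counts.values())
    for c in sorted(targets, key=lambda c: targets[c] - np.floor(targets[c]), reverse=True)[:short]:
        counts[c] += 1
    order = np.argsort(_rng(spec.seed, _GRID).random(n), kind="stable")
    labels = np.empty(n, dtype=np.int8)
    pos = 0
    for cls in spec.class_fractions:
        labels[order[pos : pos + counts[cls]]] = PFT_CLASSES.index(cls)
        pos += counts[cls]
    return PFTGrid(labels.reshape(spec.n_rows, spec.n_cols), spec.pixel_size)


def generate_gridded_ndvi(grid: PFTGrid, per_class_specs: Mapping[str, GenSpec]) -> GriddedSeries:
    """Per-pixel NDVI stack: each pixel follows its class recipe with
    independent noise.

    All class recipes must share one timeline (start, end, cadence).
    """
    present = [cls for cls in PFT_CLASSES if grid.class_mask(cls).any()]
    missing = [cls for cls in present if cls not in per_class_specs]
    if missing:
        raise ValueError(f"missing GenSpec for grid classes: {missing}")
    timelines = {
        (s.start_year, s.end_year, s.cadence) for s in per_class_specs.values()
    }
    if len(timelines) != 1:
        raise ValueError(f"class specs must share one timeline, got {sorted(timelines)}")
    any_spec = next(iter(per_class_specs.values()))
    t = any_spec.timestamps()
    values = np.empty((t.size, *grid.shape))
    rng = _rng(any_spec.seed, _GRIDDED)
    for cls in present:
        spec = per_class_specs[cls]
        m = grid.class_mask(cls)
        curve = spec.deterministic_curve(t)
        block = np.broadcast_to(curve[:, None], (t.size, int(m.sum()))).copy()
        if spec.noise_sd > 0:
            block += rng.normal(0.0, spec.noise_sd, size=block.shape)
        values[:, m] = block
    n_clip = int(np.sum((values < -1) | (values > 1)))
    if n_clip:
        logger.info("clipped %d gridded NDVI samples to [-1, 1]", n_clip)
    values = np.clip(values, -1.0, 1.0)
    return GriddedSeries(t, values, grid, "NDVI")


def generate_wildfire_events(
    rate_per_year: float,
    area_log_mean: float,
    area_log_sd: float,
    years: Iterable[int],
    seed: int = 0,
    forest_fraction: float = 0.9,
    green_biomass_density: float = 293.0,
    emission_factors: tuple[tuple[float, float], ...] = ((0.5, 0.5), (0.2, 0.5)),
) -> list[WildfireEvent]:
    """Poisson event counts per year with lognormal burnt areas (ha)."""
    if rate_per_year < 0:
        raise ValueError("rate_per_year must be >= 0")
    if area_log_sd < 0:
        raise ValueError("area_log_sd must be >= 0")
    rng = _rng(seed, _EVENTS)
    events: list[WildfireEvent] = []
    for year in years:
        for _ in range(int(rng.poisson(rate_per_year))):
            area = float(rng.lognormal(area_log_mean, area_log_sd))
            events.append(
                WildfireEvent(
                    area=area,
                    forest_fraction=forest_fraction,
                    green_biomass_density=green_biomass_density,
                    emission_factors=emission_factors,
                    year=int(year),
                )
            )
    return events
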