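"""Per-pixel anomaly mapping and atmospheric-mixing smoothing.

Gridded drivers plus a categorical vegetation map yield a per-pixel anomaly
field; a radius-parameterized kernel mean emulates transport and mixing of
emissions between neighbouring pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

from .drivers import (
    BiomassModel,
    FactorSeries,
    ResponseParams,
    co2_activity,
    isoprene_to_total,
    soil_moisture_contribution,
    temperature_activity,
)

PFT_CLASSES = ("forest", "agriculture", "grassland", "urban", "other")

#: classes whose pixels carry no biomass model and are masked out
NONVEGETATED = ("other",)

#: default substitution for classes without their own biomass regression
DEFAULT_CLASS_MODEL_MAP = {"urban": "agriculture"}

DEFAULT_PIXEL_SIZE = 500.0  # metres

KERNELS = ("disc", "gaussian")


@dataclass(frozen=True)
class PFTGrid:
    """Categorical vegetation map: integer codes into :data:`PFT_CLASSES`."""

    labels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    geotransform: tuple[float, float] = (0.0, 0.0)  # x/y origin, metres

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer code array")
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if lab.min() < 0 or lab.max() >= len(PFT_CLASSES):
            raise ValueError(f"label codes must index into {PFT_CLASSES}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_mask(self, pft_class: str) -> np.ndarray:
        return self.labels == PFT_CLASSES.index(pft_class)

    def class_fractions(self) -> dict[str, float]:
        n = self.labels.size
        return {
            cls: float((self.labels == code).sum()) / n
            for code, cls in enumerate(PFT_CLASSES)
            if (self.labels == code).any()
        }


@dataclass(frozen=True)
class GridField:
    """A 2-D anomaly field on the same geometry as its source grid.

    Masked pixels are NaN.
    """

    values: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    geotransform: tuple[float, float] = (0.0, 0.0)
    units: str = "fraction"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("field must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass(frozen=True)
class GriddedSeries:
    """A stack of per-pixel time series sharing one timeline and grid."""

    timestamps: np.ndarray  # decimal years
    values: np.ndarray  # (time, y, x)
    grid: PFTGrid
    kind: str = "NDVI"

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if v.ndim != 3 or v.shape[0] != t.size:
            raise ValueError("values must have shape (time, y, x) matching timestamps")
        if v.shape[1:] != self.grid.shape:
            raise ValueError(
                f"grid geometry mismatch: stack is {v.shape[1:]}, grid is {self.grid.shape}"
            )

    def year_mean(self, year: int) -> np.ndarray:
        mask = np.floor(self.timestamps).astype(int) == int(year)
        if not mask.any():
            raise ValueError(f"gridded series does not cover year {year}")
        return self.values[mask].mean(axis=0)

    def class_mean_series(self, pft_class: str) -> FactorSeries:
        """Spatial-mean series over one class's pixels."""
        m = self.grid.class_mask(pft_class)
        if not m.any():
            raise ValueError(f"grid has no pixels of class {pft_class!r}")
        return FactorSeries(self.timestamps, self.values[:, m].mean(axis=1), self.kind)


def pixel_anomaly(
    ndvi: GriddedSeries,
    pft: PFTGrid,
    biomass_model: BiomassModel,
    params: ResponseParams,
    temperature: FactorSeries,
    co2: FactorSeries,
    soil_moisture: FactorSeries,
    reference_year: int,
    target_year: Optional[int] = None,
    include_interaction: bool = True,
    class_model_map: Optional[Mapping[str, str]] = None,
) -> GridField:
    """Net anomaly per pixel between ``reference_year`` and ``target_year``.

    Biomass change comes from the pixel's own NDVI through its class's
    regression; the environmental drivers are spatially uniform series.
    Pixels of non-vegetated classes are masked (NaN).
    """
    if ndvi.grid.shape != pft.shape:
        raise ValueError(f"geometry mismatch: NDVI stack {ndvi.grid.shape} vs PFT {pft.shape}")
    class_model_map = dict(DEFAULT_CLASS_MODEL_MAP if class_model_map is None else class_model_map)
    if target_year is None:
        target_year = int(np.floor(ndvi.timestamps).astype(int).max())

    dt = temperature.at_year(target_year) - temperature.at_year(reference_year)
    t_c = temperature_activity(dt, params.beta_t)
    ratio = co2.at_year(target_year) / co2.at_year(reference_year)
    co2_c = isoprene_to_total(co2_activity(ratio, params.beta_co2), params.isoprene_share)
    sm_c = soil_moisture_contribution(
        soil_moisture.at_year(target_year), soil_moisture.at_year(reference_year)
    )
    env = t_c + co2_c + sm_c

    ref = ndvi.year_mean(reference_year)
    now = ndvi.year_mean(target_year)
    out = np.full(pft.shape, np.nan)
    for code, cls in enumerate(PFT_CLASSES):
        m = pft.labels == code
        if not m.any() or cls in NONVEGETATED:
            continue
        model_cls = class_model_map.get(cls, cls)
        if model_cls not in biomass_model.intercepts:
            raise ValueError(f"no biomass model for class {cls!r} (mapped to {model_cls!r})")
        lo, hi = biomass_model.ndvi_range
        b_ref = biomass_model.intercepts[model_cls] + biomass_model.slopes[model_cls] * np.clip(ref[m], lo, hi)
        b_now = biomass_model.intercepts[model_cls] + biomass_model.slopes[model_cls] * np.clip(now[m], lo, hi)
        b_c = (b_now - b_ref) / b_ref
        net = b_c + env
        if include_interaction:
            net = net + b_c * env
        out[m] = net
    return GridField(out, pft.pixel_size, pft.geotransform)


def _disc_kernel(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius_px**2).astype(float)


def smooth_field(
    field: GridField,
    radius_km: float,
    kernel: str = "disc",
    boundary: str = "renormalize",
) -> GridField:
    """Isotropic kernel mean emulating transport/mixing over ``radius_km``.

    Masked (NaN) pixels are excluded from both numerator and denominator and
    stay masked in the output.  ``boundary='renormalize'`` truncates the
    kernel at the edge and renormalizes; ``boundary='wrap'`` treats the grid
    as periodic (exact sum conservation, used by tests).
    """
    if radius_km < 0:
        raise ValueError("radius must be >= 0")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")
    if radius_km == 0:
        return GridField(field.values.copy(), field.pixel_size, field.geotransform, field.units)
    radius_px = radius_km * 1000.0 / field.pixel_size
    valid = np.isfinite(field.values)
    filled = np.where(valid, field.values, 0.0)
    mode = {"renormalize": "constant", "wrap": "wrap"}.get(boundary)
    if mode is None:
        raise ValueError(f"unknown boundary {boundary!r}")
    if kernel == "disc":
        k = _disc_kernel(radius_px)
        num = ndimage.convolve(filled, k, mode=mode, cval=0.0)
        den = ndimage.convolve(valid.astype(float), k, mode=mode, cval=0.0)
    else:
        sigma = radius_px / 2.0
        num = ndimage.gaussian_filter(filled, sigma, mode=mode, cval=0.0)
        den = ndimage.gaussian_filter(valid.astype(float), sigma, mode=mode, cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[~valid] = np.nan
    return GridField(out, field.pixel_size, field.geotransform, field.units)
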