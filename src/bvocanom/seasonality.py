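"""Seasonal-amplitude change and its translation into emission amplification.

Intra-year amplitude is half the raw min-max range per calendar year (no
harmonic fit).  The temperature-driven seasonal amplification uses the same
exponential response as the trend analysis; the biomass-driven part is a
configurable proportionality on the seasonal NDVI increase.  The two parts
add (not compound) into the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .drivers import FactorSeries, temperature_activity

#: percent seasonal biomass increase per percent seasonal NDVI increase
DEFAULT_NDVI_BIOMASS_SEASONAL_COEFF = 6.13 / 9.5


@dataclass(frozen=True)
class SeasonalSummary:
    """Per-year intra-year amplitude of one driver and its change over the span."""

    years: np.ndarray
    amplitudes: np.ndarray  # (max - min)/2 per year
    amplitude_change: float  # OLS trend of amplitudes x span, driver units
    range_change: float  # change of the full min-max range (= 2 x amplitude_change)
    kind: str = "temperature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")


class SeasonalAmplification(NamedTuple):
    temperature: float
    biomass: float
    total: float


def seasonal_amplitude(series: FactorSeries) -> SeasonalSummary:
    """Per-year amplitude (half the intra-year range) and its trend.

    Requires at least 2 complete calendar years sampled at >= 4 points/year.
    ``amplitude_change`` is the OLS slope of the yearly amplitudes times the
    span in years; ``range_change`` is twice that (full-range convention).
    """
    cadence = series.cadence
    if cadence < 4:
        raise ValueError(f"need >= 4 samples/year for seasonal analysis, series has {cadence}")
    yrs = np.floor(series.timestamps).astype(int)
    amp_years, amps = [], []
    for y in np.unique(yrs):
        m = yrs == y
        if m.sum() < cadence:  # skip partial years
            continue
        v = series.values[m]
        amp_years.append(y)
        amps.append((v.max() - v.min()) / 2.0)
    if len(amp_years) < 2:
        raise ValueError("need at least 2 complete calendar years")
    amp_years_arr = np.asarray(amp_years)
    amps_arr = np.asarray(amps)
    slope = float(np.polyfit(amp_years_arr, amps_arr, 1)[0])
    span = float(amp_years_arr[-1] - amp_years_arr[0])
    return SeasonalSummary(amp_years_arr, amps_arr, slope * span, 2.0 * slope * span, series.kind)


def fluctuation_increase(min_trend_increase: float, max_trend_increase: float) -> float:
    """Change in the seasonal min-max fluctuation from the two extreme trends.

    E.g. minima warming by 1.65 degC while maxima warm by 2.15 degC widens the
    seasonal temperature fluctuation by 0.5 degC.
    """
    return max_trend_increase - min_trend_increase


def ndvi_seasonal_to_biomass(
    ndvi_seasonal_change: float,
    coeff: float = DEFAULT_NDVI_BIOMASS_SEASONAL_COEFF,
) -> float:
    """Seasonal biomass (and emission) change from a seasonal NDVI change."""
    if coeff < 0:
        raise ValueError("coefficient must be >= 0")
    return ndvi_seasonal_change * coeff


def seasonal_amplification(
    temp_amplitude_change: float,
    beta: float = 0.1,
    biomass_seasonal_change: float = 0.0,
) -> SeasonalAmplification:
    """Seasonal emission amplification from its temperature and biomass parts.

    The temperature part is ``exp(beta * dA) - 1``; the total is the plain sum
    of the two parts.
    """
    t_part = temperature_activity(temp_amplitude_change, beta)
    return SeasonalAmplification(t_part, biomass_seasonal_change, t_part + biomass_seasonal_change)
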