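"""Assembly of per-driver contributions into the net emission anomaly.

Combines biomass, temperature, CO2 and soil-moisture contributions with a
biomass-environment interaction term, propagates per-driver error margins,
builds smoothed anomaly time series relative to a reference year, and
summarizes piecewise linear trends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .drivers import (
    BiomassModel,
    ContributionSet,
    FactorSeries,
    ResponseParams,
    biomass_contribution,
    co2_activity,
    isoprene_to_total,
    ndvi_to_biomass,
    soil_moisture_contribution,
    temperature_activity,
)

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_YEAR = 1978

ERROR_METHODS = ("linear_sum", "quadrature")


@dataclass(frozen=True)
class AnomalySeries:
    """Yearly fractional emission anomaly relative to a reference year.

    The value at the reference year is 0 when the series is built from
    drivers; derived series (e.g. moving averages) keep the reference tag but
    may smooth that point away.
    """

    years: np.ndarray
    values: np.ndarray
    reference_year: int = DEFAULT_REFERENCE_YEAR

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=int)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", y)
        object.__setattr__(self, "values", v)
        if y.ndim != 1 or v.shape != y.shape:
            raise ValueError("years and values must be 1-D arrays of equal length")
        if y.size > 1 and not np.all(np.diff(y) > 0):
            raise ValueError("years must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite anomaly values")

    def __len__(self) -> int:
        return int(self.years.size)

    def value_at(self, year: int) -> float:
        idx = np.nonzero(self.years == int(year))[0]
        if idx.size == 0:
            raise ValueError(f"year {year} not in series")
        return float(self.values[idx[0]])

    def rereference(self, new_reference_year: int) -> "AnomalySeries":
        """Express the series relative to another year, multiplicatively.

        ``new = (1 + old) / (1 + old[new_ref]) - 1`` — exact for each
        individual multiplicative driver, first-order for the combined sum.
        """
        base = 1.0 + self.value_at(new_reference_year)
        return AnomalySeries(self.years, (1.0 + self.values) / base - 1.0, int(new_reference_year))


@dataclass(frozen=True)
class ErrorBudget:
    """Per-driver relative error margins and the propagation method."""

    margins: Mapping[str, float] = field(
        default_factory=lambda: {
            "biomass": 0.03,
            "temperature": 0.03,
            "soil_moisture": 0.10,
            "co2": 0.20,
        }
    )
    method: str = "linear_sum"

    def __post_init__(self) -> None:
        for k, m in self.margins.items():
            if m < 0:
                raise ValueError(f"margin for {k!r} must be >= 0")
        if self.method not in ERROR_METHODS:
            raise ValueError(f"unknown error method {self.method!r}; expected one of {ERROR_METHODS}")


def interaction_term(biomass_c: float, env_contributions: Sequence[float] | Mapping[str, float]) -> float:
    """Cross term for environmental effects acting on the added biomass.

    ``biomass * sum(environmental contributions)`` — the first-order cross
    term of the multiplicative combination.
    """
    if isinstance(env_contributions, Mapping):
        env_sum = sum(env_contributions.values())
    else:
        env_sum = sum(env_contributions)
    return biomass_c * env_sum


def combine_contributions(c: ContributionSet, include_interaction: bool = True) -> float:
    """Net anomaly: sum of the four contributions, plus the interaction term."""
    members = (c.biomass, c.temperature, c.co2, c.soil_moisture)
    if not all(math.isfinite(m) for m in members):
        raise ValueError("non-finite contribution member")
    net = sum(members)
    if include_interaction:
        net += interaction_term(c.biomass, (c.temperature, c.co2, c.soil_moisture))
    return float(net)


def propagate_errors(
    c: ContributionSet,
    budget: Optional[ErrorBudget] = None,
    method: Optional[str] = None,
    include_interaction: bool = False,
) -> float:
    """Half-width of the net anomaly under per-driver relative margins.

    ``linear_sum`` adds absolute per-driver terms ``|contribution| * margin``;
    ``quadrature`` combines them root-sum-square.  With
    ``include_interaction`` the interaction term's first-order sensitivity is
    added: the biomass margin scaled by the environmental sum plus each
    environmental margin scaled by the biomass contribution.
    """
    budget = budget or ErrorBudget()
    method = method or budget.method
    if method not in ERROR_METHODS:
        raise ValueError(f"unknown error method {method!r}; expected one of {ERROR_METHODS}")
    contributions = {
        "biomass": c.biomass,
        "temperature": c.temperature,
        "co2": c.co2,
        "soil_moisture": c.soil_moisture,
    }
    missing = [k for k in contributions if k not in budget.margins]
    if missing:
        raise ValueError(f"margins missing for drivers: {missing}")
    terms = {k: abs(v) * budget.margins[k] for k, v in contributions.items()}
    if include_interaction:
        # d(b*e) = e*db + b*de with db = m_b*|b| and de_i = m_i*|c_i|
        env = c.environmental
        terms["interaction"] = abs(env) * budget.margins["biomass"] * abs(c.biomass) + abs(
            c.biomass
        ) * (
            budget.margins["temperature"] * abs(c.temperature)
            + budget.margins["co2"] * abs(c.co2)
            + budget.margins["soil_moisture"] * abs(c.soil_moisture)
        )
    vals = np.array(list(terms.values()))
    if method == "linear_sum":
        return float(vals.sum())
    return float(np.sqrt((vals**2).sum()))


# ---------------------------------------------------------------------------
# series assembly

def contributions_for_year(
    year: int,
    ndvi: Mapping[str, FactorSeries],
    temperature: FactorSeries,
    co2: FactorSeries,
    soil_moisture: FactorSeries,
    biomass_model: BiomassModel,
    params: ResponseParams,
    class_weights: Mapping[str, float],
    reference_year: int,
) -> ContributionSet:
    """Per-driver contributions of one year relative to the reference year."""
    changes = {}
    for cls, series in ndvi.items():
        b_ref = ndvi_to_biomass(series.at_year(reference_year), cls, biomass_model)
        b_now = ndvi_to_biomass(series.at_year(year), cls, biomass_model)
        if b_ref <= 0:
            raise ValueError(f"reference biomass for class {cls!r} is not positive")
        changes[cls] = (b_now - b_ref) / b_ref
    _, parts = biomass_contribution(changes, {c: class_weights[c] for c in changes})
    dt = temperature.at_year(year) - temperature.at_year(reference_year)
    t_c = temperature_activity(dt, params.beta_t)
    ratio = co2.at_year(year) / co2.at_year(reference_year)
    co2_c = isoprene_to_total(co2_activity(ratio, params.beta_co2), params.isoprene_share)
    sm_c = soil_moisture_contribution(soil_moisture.at_year(year), soil_moisture.at_year(reference_year))
    return ContributionSet(parts, t_c, co2_c, sm_c)


def anomaly_series(
    ndvi: Mapping[str, FactorSeries],
    temperature: FactorSeries,
    co2: FactorSeries,
    soil_moisture: FactorSeries,
    biomass_model: BiomassModel,
    params: ResponseParams,
    class_weights: Mapping[str, float],
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    include_interaction: bool = True,
) -> AnomalySeries:
    """Yearly net anomaly relative to ``reference_year``.

    All driver series must cover every requested year; the value at the
    reference year is exactly 0 by construction.
    """
    named = {"temperature": temperature, "co2": co2, "soil_moisture": soil_moisture}
    named.update({f"NDVI[{cls}]": s for cls, s in ndvi.items()})
    spans = {name: s.year_span() for name, s in named.items()}
    start = min(lo for lo, _ in spans.values())
    end = max(hi for _, hi in spans.values())
    offenders = {name: span for name, span in spans.items() if span != (start, end)}
    if offenders:
        raise ValueError(
            f"drivers do not cover the full span {start}-{end}: {offenders}"
        )
    if not start <= reference_year <= end:
        raise ValueError(
            f"reference year {reference_year} outside driver span {start}-{end}"
        )
    missing = [c for c in ndvi if c not in class_weights]
    if missing:
        raise ValueError(f"class weights missing for classes: {missing}")
    years = np.arange(start, end + 1)
    values = np.empty(years.size)
    for i, y in enumerate(years):
        c = contributions_for_year(
            int(y), ndvi, temperature, co2, soil_moisture, biomass_model, params,
            class_weights, reference_year,
        )
        values[i] = combine_contributions(c, include_interaction)
    values[years == reference_year] = 0.0  # exact by construction, clear any roundoff
    return AnomalySeries(years, values, int(reference_year))


def moving_average(series: AnomalySeries, window: int) -> AnomalySeries:
    """Centered moving average with a shrinking window at the boundaries.

    Length-preserving: each point averages indices ``i - (w-1)//2`` through
    ``i + w//2`` truncated to the series.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    v = series.values
    left, right = (window - 1) // 2, window // 2
    out = np.array(
        [v[max(0, i - left): i + right + 1].mean() for i in range(v.size)]
    )
    return AnomalySeries(series.years, out, series.reference_year)


def piecewise_slopes(
    series: AnomalySeries, breakpoints: Sequence[int]
) -> list[tuple[int, int, float]]:
    """Ordinary-least-squares slope per segment, in percent per year.

    Segments run between consecutive boundaries (series start, breakpoints,
    series end), endpoints inclusive; each needs at least 3 points.
    """
    years = series.years
    bps = sorted(int(b) for b in breakpoints)
    for b in bps:
        if not years[0] <= b <= years[-1]:
            raise ValueError(f"breakpoint {b} outside series span {years[0]}-{years[-1]}")
    if bps != sorted(set(bps)):
        raise ValueError("breakpoints must be distinct")
    bounds = [int(years[0]), *bps, int(years[-1])]
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mask = (years >= lo) & (years <= hi)
        if mask.sum() < 3:
            raise ValueError(f"segment {lo}-{hi} has fewer than 3 points")
        slope = np.polyfit(years[mask], series.values[mask], 1)[0]
        out.append((lo, hi, float(slope) * 100.0))
    return out
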