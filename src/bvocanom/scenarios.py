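"""Backcast and projection of the anomaly from temperature and CO2 alone.

Outside the satellite era only climatological drivers are available, so the
anomaly is reconstructed from a trajectory of temperature offsets and CO2
concentration ratios, with biomass adjusted proportionally to temperature.
The same contribution assembly as the main attribution path is used
throughout (single code path).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .attribution import AnomalySeries, combine_contributions, moving_average
from .drivers import (
    ContributionSet,
    ResponseParams,
    co2_activity,
    isoprene_to_total,
    temperature_activity,
)

#: biomass contribution per degC of warming, calibrated from the satellite-era
#: run (0.24 total biomass contribution over 1.88 degC of warming)
DEFAULT_TEMP_BIOMASS_COUPLING = 0.24 / 1.88

#: illustrative trajectories shipped with the package
BUILTIN_TRAJECTORIES = (
    "stable_19th_century",
    "co2_rise_1900_1978",
    "strong_warming",
    "carbon_neutral_2045",
)


@dataclass(frozen=True)
class ScenarioTrajectory:
    """Temperature offsets (degC) and CO2 ratios versus a reference state."""

    years: np.ndarray
    delta_t: np.ndarray
    co2_ratio: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=int)
        dt = np.asarray(self.delta_t, dtype=float)
        r = np.asarray(self.co2_ratio, dtype=float)
        for name, arr in (("years", y), ("delta_t", dt), ("co2_ratio", r)):
            object.__setattr__(self, name, arr)
        if dt.shape != y.shape or r.shape != y.shape:
            raise ValueError("years, delta_t and co2_ratio must have equal length")
        if y.size > 1 and not np.all(np.diff(y) > 0):
            raise ValueError("years must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("CO2 ratios must be > 0")
        if not (np.all(np.isfinite(dt)) and np.all(np.isfinite(r))):
            raise ValueError("non-finite trajectory values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "ScenarioTrajectory":
        return cls(df["year"].to_numpy(), df["delta_t_c"].to_numpy(), df["co2_ratio"].to_numpy(), label)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ScenarioTrajectory":
        return cls.from_frame(pd.read_csv(path), label or str(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "delta_t_c": self.delta_t, "co2_ratio": self.co2_ratio})


def builtin_trajectory(name: str) -> ScenarioTrajectory:
    """Load one of the packaged illustrative trajectories."""
    if name not in BUILTIN_TRAJECTORIES:
        raise ValueError(f"unknown trajectory {name!r}; expected one of {BUILTIN_TRAJECTORIES}")
    text = resources.files("bvocanom.data.trajectories").joinpath(f"{name}.csv").read_text()
    return ScenarioTrajectory.from_frame(pd.read_csv(io.StringIO(text)), name)


class ReversalResult(NamedTuple):
    year: int
    uncertainty: float  # half-width of the sigma-band of candidate years
    flag: str  # "", "no interior minimum", or "ambiguous minima"


def _trajectory_anomaly(
    traj: ScenarioTrajectory,
    params: ResponseParams,
    temp_biomass_coupling: float,
    include_interaction: bool,
) -> np.ndarray:
    values = np.empty(traj.years.size)
    for i, (dt, ratio) in enumerate(zip(traj.delta_t, traj.co2_ratio)):
        c = ContributionSet(
            biomass_parts={"all": temp_biomass_coupling * dt},
            temperature=temperature_activity(dt, params.beta_t),
            co2=isoprene_to_total(co2_activity(ratio, params.beta_co2), params.isoprene_share),
            soil_moisture=0.0,
        )
        values[i] = combine_contributions(c, include_interaction)
    return values


def reconstruct_history(
    traj: ScenarioTrajectory,
    params: Optional[ResponseParams] = None,
    temp_biomass_coupling: float = DEFAULT_TEMP_BIOMASS_COUPLING,
    reference_year: Optional[int] = None,
    include_interaction: bool = True,
) -> AnomalySeries:
    """Anomaly series implied by a temperature/CO2 trajectory.

    By default the reference year is the (first) trajectory year at the
    reference state (zero offset, unit ratio); otherwise the series is
    re-referenced multiplicatively to ``reference_year``.
    """
    params = params or ResponseParams()
    values = _trajectory_anomaly(traj, params, temp_biomass_coupling, include_interaction)
    if reference_year is None:
        at_ref_state = (traj.delta_t == 0) & (traj.co2_ratio == 1)
        ref = int(traj.years[np.argmax(at_ref_state)]) if at_ref_state.any() else int(traj.years[0])
    else:
        ref = int(reference_year)
        if ref not in traj.years:
            raise ValueError(f"reference year {ref} outside trajectory span "
                             f"{traj.years[0]}-{traj.years[-1]}")
    series = AnomalySeries(traj.years, values, ref)
    if abs(series.value_at(ref)) > 0:
        series = series.rereference(ref)
    return series


def detect_reversal_year(
    series: AnomalySeries,
    smoothing_window: int = 7,
    noise_sd: Optional[float] = None,
) -> ReversalResult:
    """Year of the global minimum of the smoothed series.

    Uncertainty is the half-width of the set of years whose smoothed value
    lies within one noise sigma of the minimum (sigma estimated from the
    raw-minus-smoothed residuals when not given).  Monotone series return the
    end-point with a flag; equally deep minima farther apart than the
    uncertainty are flagged and the earliest is returned.
    """
    if len(series) <= smoothing_window:
        raise ValueError("series must be longer than the smoothing window")
    smoothed = moving_average(series, smoothing_window)
    v = smoothed.values
    i = int(np.argmin(v))
    if noise_sd is None:
        noise_sd = float(np.std(series.values - v))
    band = series.years[v <= v[i] + noise_sd]
    uncertainty = float(band.max() - band.min()) / 2.0
    flag = ""
    if i == 0 or i == v.size - 1:
        flag = "no interior minimum"
    else:
        ties = series.years[v == v[i]]
        if ties.size > 1 and (ties.max() - ties.min()) > 2 * max(uncertainty, 0.5):
            flag = "ambiguous minima"
    return ReversalResult(int(series.years[i]), uncertainty, flag)


def project_future(
    traj: ScenarioTrajectory,
    params: Optional[ResponseParams] = None,
    horizon_end: Optional[int] = None,
    temp_biomass_coupling: float = DEFAULT_TEMP_BIOMASS_COUPLING,
    reference_year: Optional[int] = None,
    include_interaction: bool = True,
) -> tuple[AnomalySeries, float]:
    """Anomaly projection and its mean annual rate (OLS slope, %/yr)."""
    params = params or ResponseParams()
    if horizon_end is None:
        horizon_end = int(traj.years[-1])
    if horizon_end < traj.years[0]:
        raise ValueError(f"horizon end {horizon_end} precedes trajectory start {traj.years[0]}")
    if horizon_end > traj.years[-1]:
        raise ValueError(f"trajectory ends {traj.years[-1]}, before horizon end {horizon_end}")
    series = reconstruct_history(traj, params, temp_biomass_coupling, reference_year, include_interaction)
    m = series.years <= horizon_end
    if m.sum() < 2:
        raise ValueError("horizon must contain at least 2 years")
    rate = float(np.polyfit(series.years[m], series.values[m], 1)[0]) * 100.0
    return AnomalySeries(series.years[m], series.values[m], series.reference_year), rate
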