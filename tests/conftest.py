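import numpy as np
import pytest

from bvocanom.config import load_worked_examples
from bvocanom.drivers import BiomassModel, ContributionSet, FactorSeries, ResponseParams

REF_YEAR = 1978
END_YEAR = 2024

#: class area weights used throughout the synthetic fixtures (roughly one
#: third forest, half agriculture)
CLASS_WEIGHTS = {"forest": 1 / 3, "agriculture": 0.5, "grassland": 1 / 6}


@pytest.fixture(scope="session")
def worked():
    return load_worked_examples()


@pytest.fixture(scope="session")
def params():
    return ResponseParams()


@pytest.fixture(scope="session")
def printed_contributions(worked):
    """The four printed per-driver contributions (headline biomass 0.24)."""
    c = worked["contributions"]
    return ContributionSet(
        biomass_parts={"total": c["biomass"]},
        temperature=c["temperature"],
        co2=c["co2"],
        soil_moisture=c["soil_moisture"],
    )


def linear_series(kind, start, end, v0, v1, noise_sd=0.0, seed=0):
    """Annual series moving linearly from v0 (at start) to v1 (at end)."""
    years = np.arange(start, end + 1, dtype=float)
    values = v0 + (v1 - v0) * (years - start) / (end - start)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, years.size)
    return FactorSeries(years, values, kind)


def prescribed_drivers(worked, noise=None, seed=0):
    """Driver set whose endpoint contributions match the printed values.

    NDVI per class is built through a zero-intercept biomass model so the
    relative biomass change at 2024 equals part/weight for each class;
    temperature, CO2-ratio and soil-moisture series move linearly to the
    printed endpoint changes.  ``noise`` maps driver name -> noise sd.
    """
    noise = noise or {}
    parts = worked["contributions"]["biomass_parts"]
    model = BiomassModel(
        intercepts={c: 0.0 for c in parts},
        slopes={c: 100.0 for c in parts},
        ndvi_range=(0.01, 0.9),
    )
    ndvi = {}
    for i, (cls, part) in enumerate(parts.items()):
        change = part / CLASS_WEIGHTS[cls]
        ndvi[cls] = linear_series(
            "NDVI", REF_YEAR, END_YEAR, 0.5, 0.5 * (1 + change),
            noise.get("NDVI", 0.0), seed=seed * 10 + i,
        )
    temperature = linear_series(
        "temperature", REF_YEAR, END_YEAR, 8.0, 8.0 + worked["temperature_trend_c"],
        noise.get("temperature", 0.0), seed=seed * 10 + 5,
    )
    co2 = linear_series(
        "CO2", REF_YEAR, END_YEAR, 1.0, worked["co2_ratio"],
        noise.get("CO2", 0.0), seed=seed * 10 + 6,
    )
    sm = linear_series(
        "soil_moisture", REF_YEAR, END_YEAR, 0.30,
        0.30 * (1 + worked["soil_moisture_relative_anomaly"]),
        noise.get("soil_moisture", 0.0), seed=seed * 10 + 7,
    )
    return {"ndvi": ndvi, "temperature": temperature, "co2": co2,
            "soil_moisture": sm, "biomass_model": model,
            "class_weights": CLASS_WEIGHTS}
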