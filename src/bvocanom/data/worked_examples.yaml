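# In-text worked-example inputs for the 1979-2024 attribution run.
# All contributions are dimensionless fractions relative to the 1978 reference.
contributions:
  # headline biomass contribution (the per-class parts below sum to 0.2404
  # and are reported rounded to 24%; the net-anomaly arithmetic uses 0.24)
  biomass: 0.24
  biomass_parts:
    forest: 0.0834
    agriculture: 0.1405
    grassland: 0.0165
  temperature: 0.207
  co2: 0.085
  soil_moisture: -0.0528
error_margins:
  biomass: 0.03
  temperature: 0.03
  soil_moisture: 0.10
  co2: 0.20
temperature_trend_c: 1.88
co2_ratio: 0.62
soil_moisture_relative_anomaly: -0.0528
wildfire_event:
  area_ha: 4840
  forest_fraction: 0.9
  green_biomass_density_t_ha: 293
  emission_factors: [[0.5, 0.5], [0.2, 0.5]]
  # the per-area-rate figure implies roughly this burn duration; it is an
  # assumption of this artifact, not a reported value
  duration_days: 19.2
seasonal:
  min_temp_increase_c: 1.65
  max_temp_increase_c: 2.15
  ndvi_seasonal_increase_pct: 9.5
  biomass_seasonal_increase_pct: 6.13
reference_year: 1978
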