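# File formats

All tabular interfaces are plain UTF-8 CSV with a header row, ISO-8601
dates (`YYYY-MM-DD`), ISO timestamps for sub-daily data, and decimal
points. Readers in `streamghg.io` validate columns and raise a
`SchemaError` naming the file and the missing columns.

## Input bundle (one directory, read by `streamghg.io.read_inputs`)

| file | columns | notes |
|---|---|---|
| `profile.csv` | `branch_id, distance_m, elevation_m, drainage_km2, width_m` | longitudinal profile; distance increases downstream within a branch |
| `topology.csv` | `branch_id, downstream_branch_id` | each branch drains into the head (distance 0) of its parent; empty parent marks the outlet branch |
| `stations.csv` | `station_id, date, q_Ls, drainage_km2` | daily mean discharge per gauging station |
| `station_locations.csv` | `station_id, branch_id, distance_m` | optional; enables nearest-station temperature assignment |
| `injections.csv` | `reach_id, date, length_m, width_m, depth_m, slope_pct, travel_time_min, c_up, c_down, q_mean_Ls, q_diff_pct, water_temp_C` | one row per downstream tracer sampling replicate; `c_up`/`c_down` are relative propane concentrations |
| `surveys.csv` | `point_id, branch_id, distance_m, date, gas, conc_uM` | spatial concentration campaigns (`gas` is `CH4` or `CO2`) |
| `anchors.csv` | `anchor_id, branch_id, distance_m` | temporally resolved stations |
| `anchor_ch4.csv` | `anchor_id, date, conc` | biweekly CH4 bottle samples (uM) |
| `co2_sensors.csv` | `anchor_id, timestamp, conc_uM` | high-frequency CO2 sensor records (despiked and daily-averaged by the pipeline) |
| `air_temp.csv` | `date, temp_C` | daily mean air temperature (ice mask) |
| `water_temp.csv` | `date, temp_C` (optionally `station_id`) | daily mean water temperature |

## Outputs

* reach table (`reaches`): `reach_id, branch_id, start_m, end_m,
  midpoint_m, length_m, drop_m, slope_pct, slope_category,
  drainage_km2, width_m, area_m2`
* k600 observation table: `reach_id, date, slope_pct, q_mean_Ls,
  velocity_ms, rate_per_min, k_md, k600_md, negative_rate`
* reach-day emission table: `reach_id, date, discharge_Ls, velocity_ms,
  k600_md, water_temp_C, area_m2, slope_category, conc_CH4_uM,
  flux_CH4, mass_CH4_kg, conc_CO2_uM, flux_CO2, mass_CO2_Mg, excluded`
  — ice-masked days are present with `excluded=True`, never dropped
  silently
* emission summary: JSON (see `EmissionSummary.to_dict`)
* pipeline config: YAML with the fields of
  `streamghg.config.PipelineConfig`
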