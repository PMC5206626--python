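"""End-to-end emission upscaling: inputs -> reach-day fluxes -> summary.

The full analysis sequence, as one function: discretise the
network, fit the daily discharge/drainage-area scalings, estimate k600
from the tracer injections, fit (or take as given) the velocity and
k600 regression models and the measured-vs-modelled calibration factor,
reconstruct daily per-reach concentrations from surveys and anchor
series, mask frozen periods, and integrate diffusive fluxes into the
network emission summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import concentrations as conc_mod
from . import emissions, network as net, tracer
from .config import PipelineConfig
from .io import CatchmentInputs

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    network: net.Network
    reaches: pd.DataFrame
    day_scalings: pd.DataFrame  # date, b, r2, n_stations
    k600_observations: pd.DataFrame
    velocity_model: net.RegressionModel
    k600_model: net.RegressionModel
    calibration: float
    ratios: dict  # gas -> per-reach ratio/cv table
    uncertainty_pct: dict  # gas -> %
    states: pd.DataFrame
    summary: emissions.EmissionSummary


def _daily_scalings(stations: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for date, grp in stations.groupby("date"):
        s = net.fit_daily_scaling(
            grp["drainage_km2"].to_numpy(), grp["q_Ls"].to_numpy(), date=date
        )
        rows.append(
            {"date": date, "b": s.b, "r2": s.r2, "n_stations": s.n_stations}
        )
    return pd.DataFrame(rows).sort_values("date").reset_index(drop=True)


def _station_temp_assignment(
    inputs: CatchmentInputs, reaches: pd.DataFrame, network: net.Network
) -> pd.Series | None:
    locs = inputs.station_locations
    if locs is None or locs["distance_m"].isna().any():
        return None
    anchors_like = locs.rename(columns={"station_id": "anchor_id"})[
        ["anchor_id", "branch_id", "distance_m"]
    ]
    return conc_mod.assign_anchors(reaches, anchors_like, network)


def run_pipeline(
    inputs: CatchmentInputs, config: PipelineConfig | None = None
) -> PipelineResult:
    config = config or PipelineConfig()
    network = net.Network(profile=inputs.profile, topology=dict(inputs.topology))
    reaches = net.discretize(network, dz=config.dz)
    logger.info("discretised network into %d reaches", len(reaches))

    # --- discharge scaling ------------------------------------------------
    scalings = _daily_scalings(inputs.stations)
    cal = pd.DatetimeIndex(scalings["date"])
    b = scalings.set_index("date")["b"]

    # --- tracer campaign and regression models ----------------------------
    obs = tracer.k600_table(inputs.injections)
    n_neg = int(obs["negative_rate"].sum())
    if n_neg:
        logger.warning("%d negative-rate injection observations excluded", n_neg)
    if config.refit:
        vel_data = obs.drop_duplicates(["reach_id", "date"]).rename(
            columns={"q_mean_Ls": "q_Ls"}
        )
        velocity_model = net.fit_velocity_model(
            vel_data, slope_floor=config.slope_floor
        )
        k600_model = net.fit_k600_model(obs, slope_floor=config.slope_floor)
        good = obs.loc[~obs["negative_rate"]]
        modelled = net._k600_uncapped(
            good["velocity_ms"].to_numpy(),
            good["slope_pct"].to_numpy(),
            k600_model,
            calibration=1.0,
            bias_correct=True,
            slope_floor=config.slope_floor,
        )
        calibration = net.calibration_factor(good["k600_md"].to_numpy(), modelled)
        logger.info(
            "fitted models: velocity %s, k600 %s, calibration %.3f",
            velocity_model, k600_model, calibration,
        )
    else:
        velocity_model = config.velocity_model
        k600_model = config.k600_model
        calibration = config.calibration

    # --- per-reach-day discharge, velocity, k600 --------------------------
    b_arr = b.reindex(cal).to_numpy()
    discharge = pd.DataFrame(
        {
            rec.reach_id: b_arr * rec.drainage_km2
            for rec in reaches.itertuples(index=False)
        },
        index=cal,
    )
    velocity = {}
    k600 = {}
    for rec in reaches.itertuples(index=False):
        v = net.predict_velocity(
            discharge[rec.reach_id].to_numpy(),
            rec.slope_pct,
            model=velocity_model,
            slope_floor=config.slope_floor,
        )
        k, _ = net.predict_k600_series(
            v,
            rec.slope_pct,
            model=k600_model,
            calibration=calibration,
            v_cap=config.v_cap,
            slope_floor=config.slope_floor,
        )
        velocity[rec.reach_id] = v
        k600[rec.reach_id] = k
    velocity = pd.DataFrame(velocity, index=cal)
    k600 = pd.DataFrame(k600, index=cal)

    # --- water temperature per reach-day ----------------------------------
    wt = inputs.water_temp
    if "station_id" in wt.columns and wt["station_id"].nunique() > 1:
        assignment = _station_temp_assignment(inputs, reaches, network)
        wide = wt.pivot_table(index="date", columns="station_id", values="temp_C")
        wide = wide.reindex(cal).interpolate(method="time").ffill().bfill()
        if assignment is not None:
            water_temp = pd.DataFrame(
                {r: wide[assignment.loc[r]] for r in reaches["reach_id"]}, index=cal
            )
        else:
            mean = wide.mean(axis=1)
            water_temp = pd.DataFrame(
                {r: mean for r in reaches["reach_id"]}, index=cal
            )
    else:
        series = (
            wt.set_index("date")["temp_C"]
            .reindex(cal)
            .interpolate(method="time")
            .ffill()
            .bfill()
        )
        water_temp = pd.DataFrame(
            {r: series for r in reaches["reach_id"]}, index=cal
        )

    # --- concentrations ----------------------------------------------------
    anchor_assignment = conc_mod.assign_anchors(reaches, inputs.anchors, network)
    ratios = {}
    conc_wide = {}
    missing = {}
    unc_pct = {}

    # CO2 anchor series: despiked sensor daily means
    co2_rows = []
    for anchor_id, sensor in inputs.co2_sensors.items():
        clean = conc_mod.despike_sensor(
            sensor, threshold=config.despike_threshold, window=config.despike_window
        )
        daily = conc_mod.daily_means(clean)
        co2_rows.append(
            pd.DataFrame(
                {"anchor_id": anchor_id, "date": daily.index, "conc": daily.to_numpy()}
            )
        )
    anchor_series = {
        "CH4": inputs.anchor_ch4,
        "CO2": pd.concat(co2_rows, ignore_index=True),
    }

    for gas_name in ("CH4", "CO2"):
        survey = inputs.surveys[gas_name]
        interp_cols = {}
        anchor_cols = {}
        a_series = anchor_series[gas_name]
        filled_anchor, _ = conc_mod.fill_anchor_daily(a_series, cal)
        for date, grp in survey.groupby("date"):
            interp_cols[date] = conc_mod.spatial_interpolate(
                grp.rename(columns={"conc_uM": "conc"}), network, reaches
            )
            # anchor concentration on the survey date (gap-filled daily)
            anchor_cols[date] = pd.Series(
                {aid: float(s.loc[date]) for aid, s in filled_anchor.items()}
            )
        interpolated = pd.DataFrame(interp_cols)
        anchor_conc = pd.DataFrame(anchor_cols)
        rt = conc_mod.relative_ratios(interpolated, anchor_conc, anchor_assignment)
        ratios[gas_name] = rt
        unc_pct[gas_name] = conc_mod.uncertainty_pct(rt["cv"])
        conc_wide[gas_name], missing[gas_name] = conc_mod.temporal_reconstruct(
            a_series, rt, anchor_assignment, cal
        )

    # --- ice mask and flux integration -------------------------------------
    air = (
        inputs.air_temp.set_index("date")["temp_C"]
        .reindex(cal)
        .interpolate(method="time")
        .ffill()
        .bfill()
    )
    excluded = net.ice_mask(air)

    states = emissions.emission_table(
        reaches,
        discharge,
        velocity,
        k600,
        water_temp,
        conc_wide,
        excluded=excluded,
        missing=None,
        atm_ppm={"CH4": config.atm_ch4_ppm, "CO2": config.atm_co2_ppm},
    )
    summary = emissions.aggregate(
        states,
        ch4_uncertainty_pct=unc_pct["CH4"],
        co2_uncertainty_pct=unc_pct["CO2"],
        gwp=config.gwp,
    )
    logger.info(
        "pipeline complete: %d reach-days (%.1f%% excluded), "
        "mean annual CH4 %.3g kg, CO2 %.3g Mg",
        len(states),
        100 * summary.excluded_fraction,
        summary.mean_annual_ch4_kg,
        summary.mean_annual_co2_Mg,
    )
    return PipelineResult(
        network=network,
        reaches=reaches,
        day_scalings=scalings,
        k600_observations=obs,
        velocity_model=velocity_model,
        k600_model=k600_model,
        calibration=calibration,
        ratios=ratios,
        uncertainty_pct=unc_pct,
        states=states,
        summary=summary,
    )
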