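"""Synthetic catchments with known ground truth.

Generates every input the upscaling pipeline consumes — a branched
longitudinal profile, daily station discharge, water/air temperature,
concentration surveys, anchor series, CO2 sensor records and tracer
injections — from a single seeded scenario, together with the true
quantities the generator used (daily b, true k600 surfaces, the true
concentration field), so every pipeline stage can be tested end to end
without field data.

The default scenario mirrors the study design it emulates: a ~6 km
network of 84 fixed-drop reaches dominated by near-flat ditches
(~90% of stream area below 1% slope) with a steep tail up to ~20%,
two years of daily discharge proportional to drainage area with storm
events exceeding four times the mean, supersaturated and strongly
spatially structured gas concentrations (CH4 much more variable than
CO2), and propane injections with log10-scale noise matching the
published model mean squared errors.  With ``zero_noise=True`` every
stochastic term is switched off and the concentration field is exactly
separable, so the pipeline must reproduce the generator truth to float
tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import gases, network as net, tracer
from .io import CatchmentInputs

__all__ = [
    "CatchmentScenario",
    "gen_network",
    "gen_discharge",
    "gen_temperatures",
    "gen_concentrations",
    "simulate_injection",
    "gen_injection_study",
    "generate_catchment",
    "true_reach_day_table",
]


@dataclass(frozen=True)
class CatchmentScenario:
    """Parameters of a synthetic catchment.

    Defaults describe the emulated study conditions; ``zero_noise``
    switches every stochastic term off for exact end-to-end checks.
    """

    seed: int = 0
    zero_noise: bool = False
    start_date: str = "2013-01-01"
    n_days: int = 730

    # network geometry: three branches, two headwaters joining the main
    # stem; per-branch elevation drops (m) set the reach counts at dz.
    branch_drops: dict = field(
        default_factory=lambda: {"hw1": 14.0, "hw2": 7.0, "main": 21.0}
    )
    dz: float = 0.5
    # reaches per slope category across the whole network, shaped so the
    # areal shares land near 90/5/3/1/1 percent for S1..S5
    category_counts: dict = field(
        default_factory=lambda: {"S1": 47, "S2": 10, "S3": 10, "S4": 5, "S5": 12}
    )
    slope_ranges: dict = field(
        default_factory=lambda: {
            "S1": (0.2, 0.9),
            "S2": (1.0, 2.0),
            "S3": (2.0, 4.0),
            "S4": (4.0, 6.0),
            "S5": (6.0, 21.0),
        }
    )
    width_coef: float = 0.9  # w = coef * A_km2 ** width_exp  (m)
    width_exp: float = 0.35
    outlet_area_km2: float = 7.0

    # discharge: D = b(t) A with seasonal baseflow, storm events and a
    # wetter second year
    b_mean: float = 12.0  # L s-1 km-2
    season_amp: float = 0.45
    storm_prob: float = 0.05
    storm_mult: tuple = (3.0, 8.0)
    year2_factor: float = 1.7
    discharge_noise: float = 0.05  # station lognormal sd
    b_ar_sd: float = 0.35
    b_ar_rho: float = 0.85

    # concentrations: separable field s(x) * g(t) with per-gas spatial
    # variability (CH4 >> CO2) and multiplicative field noise
    ch4_mean_uM: float = 1.7
    co2_mean_uM: float = 131.6
    ch4_spatial_sd: float = 0.45  # log10 sd across survey points
    co2_spatial_sd: float = 0.12
    ch4_temporal_sd: float = 0.35  # lognormal sd of anchor dynamics
    co2_temporal_sd: float = 0.20
    temporal_rho: float = 0.85
    field_noise_ch4: float = 0.15  # reach-day multiplicative (lognormal sd)
    field_noise_co2: float = 0.08
    survey_noise_ch4: float = 0.35  # per-sample lognormal sd (separability+measurement)
    survey_noise_co2: float = 0.12
    n_survey_points: int = 20
    n_surveys_ch4: int = 5
    n_surveys_co2: int = 7
    sensor_spike_prob: float = 0.01
    sensor_diel_amp: float = 0.06

    # tracer injections
    n_injection_reaches: int = 6
    n_occasions: int = 21
    n_obs_per_occasion: int = 3  # brings total k600 observations to ~53
    velocity_log10_sd: float = 0.0775  # sqrt(0.006)
    k600_log10_sd: float = 0.2236  # sqrt(0.050)
    gw_fraction: float = 0.005  # 0.5% discharge gain over a reach
    max_loss_fraction: float = 0.35  # design limit on tracer loss per run

    @property
    def total_relief(self) -> float:
        """Elevation difference between the highest head and the outlet."""
        main = self.branch_drops["main"]
        hw = max(d for b, d in self.branch_drops.items() if b != "main")
        return main + hw

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _maybe(scenario: CatchmentScenario, value: float) -> float:
    return 0.0 if scenario.zero_noise else value


# ---------------------------------------------------------------------------
# network


def gen_network(scenario: CatchmentScenario) -> tuple[net.Network, pd.DataFrame]:
    """Generate the branched profile; returns (Network, true reach table).

    Reaches are built directly as fixed-drop segments whose slopes are
    drawn within their category's range, so the reach table is exact
    generator truth; the emitted profile consists of the reach boundary
    points and `network.discretize` recovers the same reaches.
    """
    rng = scenario.rng(1)
    labels = [
        cat for cat, n in scenario.category_counts.items() for _ in range(n)
    ]
    rng.shuffle(labels)
    n_total = len(labels)
    counts = {
        b: int(round(d / scenario.dz)) for b, d in scenario.branch_drops.items()
    }
    assert sum(counts.values()) == n_total, "category counts must match drops/dz"

    # per-branch drainage area ranges (km2), headwaters feeding the main stem
    area_ranges = {"hw1": (0.3, 1.4), "hw2": (0.2, 0.9)}
    area_ranges["main"] = (
        area_ranges["hw1"][1] + area_ranges["hw2"][1],
        scenario.outlet_area_km2,
    )
    topology = {"hw1": "main", "hw2": "main", "main": None}

    profile_rows = []
    pos = 0
    for branch in ("hw1", "hw2", "main"):
        n_b = counts[branch]
        branch_labels = labels[pos : pos + n_b]
        pos += n_b
        if scenario.zero_noise:
            slopes = np.array(
                [np.mean(scenario.slope_ranges[c]) for c in branch_labels]
            )
        else:
            slopes = np.array(
                [rng.uniform(*scenario.slope_ranges[c]) for c in branch_labels]
            )
        lengths = 100.0 * scenario.dz / slopes
        dist = np.concatenate(([0.0], np.cumsum(lengths)))
        total_len = dist[-1]
        head_elev = 51.0 + scenario.branch_drops["main"]
        if branch != "main":
            head_elev += scenario.branch_drops[branch]
        elev = head_elev - scenario.dz * np.arange(n_b + 1)
        a0, a1 = area_ranges[branch]
        areas = a0 + (a1 - a0) * dist / total_len
        widths = scenario.width_coef * areas**scenario.width_exp
        for d, e, a, w in zip(dist, elev, areas, widths):
            profile_rows.append(
                {
                    "branch_id": branch,
                    "distance_m": float(d),
                    "elevation_m": float(e),
                    "drainage_km2": float(a),
                    "width_m": float(w),
                }
            )
    profile = pd.DataFrame(profile_rows)
    network = net.Network(profile=profile, topology=topology)
    reaches = net.discretize(network, dz=scenario.dz)
    return network, reaches


# ---------------------------------------------------------------------------
# discharge and temperature


def _calendar(scenario: CatchmentScenario) -> pd.DatetimeIndex:
    return pd.date_range(scenario.start_date, periods=scenario.n_days, freq="D")


def gen_discharge(
    scenario: CatchmentScenario, network: net.Network
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Daily station discharge series and the true daily b.

    Returns ``(stations, true_b, station_locations)``; stations has
    columns station_id, date, q_Ls, drainage_km2.  The four gauging
    stations sit at the headwater mouths and along the main stem.
    """
    rng = scenario.rng(2)
    cal = _calendar(scenario)
    doy = cal.dayofyear.to_numpy()
    season = 1.0 + scenario.season_amp * np.sin(2 * np.pi * (doy - 110) / 365.25)
    if scenario.zero_noise:
        ar = np.zeros(len(cal))
        storm_days = np.zeros(len(cal), dtype=bool)
        storm_days[::40] = True
        storms = np.where(storm_days, 5.0, 1.0)
    else:
        eps = rng.normal(0, scenario.b_ar_sd * math.sqrt(1 - scenario.b_ar_rho**2), len(cal))
        ar = np.empty(len(cal))
        ar[0] = rng.normal(0, scenario.b_ar_sd)
        for i in range(1, len(cal)):
            ar[i] = scenario.b_ar_rho * ar[i - 1] + eps[i]
        storm_days = rng.random(len(cal)) < scenario.storm_prob
        storms = np.where(storm_days, rng.uniform(*scenario.storm_mult, len(cal)), 1.0)
    year_factor = np.where(cal.year == cal.year.min(), 1.0, scenario.year2_factor)
    b = scenario.b_mean * season * np.exp(ar) * storms * year_factor
    true_b = pd.Series(b, index=cal, name="b")

    locs = pd.DataFrame(
        [
            {"station_id": "st1", "branch_id": "hw1", "distance_m": None},
            {"station_id": "st2", "branch_id": "hw2", "distance_m": None},
            {"station_id": "st3", "branch_id": "main", "distance_m": None},
            {"station_id": "st4", "branch_id": "main", "distance_m": None},
        ]
    )
    # place stations at fixed fractions along their branches
    fracs = {"st1": 0.95, "st2": 0.6, "st3": 0.45, "st4": 0.95}
    rows = []
    for rec in locs.itertuples(index=False):
        length = network.branch_length(rec.branch_id)
        d = fracs[rec.station_id] * length
        prof = network.profile[network.profile["branch_id"] == rec.branch_id]
        area = float(
            np.interp(d, prof["distance_m"].to_numpy(), prof["drainage_km2"].to_numpy())
        )
        rows.append({"station_id": rec.station_id, "distance_m": d, "area": area})
    meta = pd.DataFrame(rows)
    locs["distance_m"] = meta["distance_m"].to_numpy()
    locs["drainage_km2"] = meta["area"].to_numpy()

    frames = []
    for rec in locs.itertuples(index=False):
        noise = (
            np.ones(len(cal))
            if scenario.zero_noise
            else np.exp(rng.normal(0, scenario.discharge_noise, len(cal)))
        )
        frames.append(
            pd.DataFrame(
                {
                    "station_id": rec.station_id,
                    "date": cal,
                    "q_Ls": b * rec.drainage_km2 * noise,
                    "drainage_km2": rec.drainage_km2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), true_b, locs


def gen_temperatures(
    scenario: CatchmentScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily air and water temperature series (deg C).

    Air temperature dips well below zero in winter, producing the >3-day
    sub-zero runs that trigger the ice mask; water temperature is
    floored just above zero and stays inside the Schmidt-number fit
    range.
    """
    rng = scenario.rng(3)
    cal = _calendar(scenario)
    doy = cal.dayofyear.to_numpy()
    base_air = 8.0 - 13.0 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    base_water = 8.5 - 8.3 * np.cos(2 * np.pi * (doy - 30) / 365.25)
    air = base_air + (0 if scenario.zero_noise else rng.normal(0, 2.5, len(cal)))
    water = np.maximum(
        0.2,
        base_water + (0 if scenario.zero_noise else rng.normal(0, 0.8, len(cal))),
    )
    air_df = pd.DataFrame({"date": cal, "temp_C": air})
    water_df = pd.DataFrame({"date": cal, "temp_C": water})
    return air_df, water_df


# ---------------------------------------------------------------------------
# concentrations


def _survey_points(
    scenario: CatchmentScenario, network: net.Network
) -> pd.DataFrame:
    """Fixed monitoring points: 20 spread over the network, 4 anchors."""
    per_branch = {"hw1": 6, "hw2": 4, "main": 10}
    rows = []
    i = 0
    for branch, n_pts in per_branch.items():
        length = network.branch_length(branch)
        for frac in np.linspace(0.08, 0.95, n_pts):
            rows.append(
                {
                    "point_id": f"p{i:02d}",
                    "branch_id": branch,
                    "distance_m": float(frac * length),
                }
            )
            i += 1
    pts = pd.DataFrame(rows).head(scenario.n_survey_points)
    anchor_ids = ["p02", "p07", "p12", "p17"]
    pts["is_anchor"] = pts["point_id"].isin(anchor_ids)
    return pts


def _interp_field(
    network: net.Network, points: pd.DataFrame, values: np.ndarray, reaches: pd.DataFrame
) -> pd.Series:
    """Generator-side linear interpolation of point values to reaches.

    Deliberately written independently of
    `concentrations.spatial_interpolate` (simple per-branch interp with
    an area-weighted virtual confluence sample) so it can act as the
    oracle for it.
    """
    pts = points.assign(conc=values)
    tables = {}
    for branch in network.topological_order():
        rows = pts[pts["branch_id"] == branch].sort_values("distance_m")
        xs = rows["distance_m"].to_numpy(dtype=float)
        cs = rows["conc"].to_numpy(dtype=float)
        parents = [p for p in network.parents_of(branch) if p in tables]
        if parents:
            vals, wts = [], []
            for p in parents:
                pxs, pcs = tables[p]
                prof = network.profile[network.profile["branch_id"] == p]
                vals.append(float(np.interp(network.branch_length(p), pxs, pcs)))
                wts.append(float(prof["drainage_km2"].max()))
            xs = np.concatenate(([0.0], xs))
            cs = np.concatenate(([np.average(vals, weights=wts)], cs))
        tables[branch] = (xs, cs)
    out = {}
    for rec in reaches.itertuples(index=False):
        xs, cs = tables[rec.branch_id]
        out[rec.reach_id] = float(np.interp(rec.midpoint_m, xs, cs))
    return pd.Series(out).rename_axis("reach_id")


def _ar1_lognormal(rng, n, sd, rho, zero_noise):
    if zero_noise or sd == 0:
        return np.ones(n)
    eps = rng.normal(0, sd * math.sqrt(1 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return np.exp(x - sd**2 / 2)


def gen_concentrations(
    scenario: CatchmentScenario, network: net.Network, reaches: pd.DataFrame
) -> dict:
    """Surveys, anchor series, CO2 sensor records and the true field.

    The true field is separable, ``conc(reach, t) = s(reach) g(t)`` times
    lognormal reach-day noise (off under ``zero_noise``).  The CH4
    temporal signal is piecewise linear between biweekly knots, so the
    anchor gap-filling step can be exact; CO2 anchors are daily means of
    hourly sensor series that carry a diel cycle and occasional
    condensation spikes (both off under ``zero_noise``).
    """
    rng = scenario.rng(4)
    cal = _calendar(scenario)
    points = _survey_points(scenario, network)
    n_pts = len(points)

    out = {"points": points}
    spatial = {}
    for gas_name, mean_uM, sp_sd in (
        ("CH4", scenario.ch4_mean_uM, scenario.ch4_spatial_sd),
        ("CO2", scenario.co2_mean_uM, scenario.co2_spatial_sd),
    ):
        # spatial pattern at the survey points: smooth downstream trend
        # plus lognormal scatter; strictly positive (supersaturated)
        trend = np.linspace(0.15, -0.15, n_pts)
        scatter = (
            np.zeros(n_pts)
            if scenario.zero_noise
            else rng.normal(0, sp_sd, n_pts)
        )
        s_points = mean_uM * 10.0 ** (trend + scatter)
        spatial[gas_name] = s_points
    out["spatial_points"] = spatial

    # temporal signals
    # CH4: biweekly knots (ice-free season), linear in between
    knots = cal[(cal.month >= 4) & (cal.month <= 11)][::14]
    g_knots = _ar1_lognormal(
        rng, len(knots), scenario.ch4_temporal_sd, scenario.temporal_rho,
        scenario.zero_noise,
    )
    if scenario.zero_noise:
        g_knots = 1.0 + 0.2 * np.sin(np.arange(len(knots)) / 3.0)
    g_ch4 = (
        pd.Series(g_knots, index=knots)
        .reindex(cal.union(knots))
        .interpolate(method="time")
        .ffill()
        .bfill()
        .reindex(cal)
    )
    # CO2: smooth seasonal signal plus AR(1) dynamics
    doy = cal.dayofyear.to_numpy()
    g_co2 = (1.0 + 0.15 * np.sin(2 * np.pi * (doy - 200) / 365.25)) * _ar1_lognormal(
        rng, len(cal), scenario.co2_temporal_sd, scenario.temporal_rho,
        scenario.zero_noise,
    )
    g_co2 = pd.Series(g_co2, index=cal)
    out["temporal"] = {"CH4": g_ch4, "CO2": g_co2}

    # true per-reach spatial values (generator-side interpolation)
    s_reach = {
        gas_name: _interp_field(network, points, spatial[gas_name], reaches)
        for gas_name in ("CH4", "CO2")
    }
    out["spatial_reaches"] = s_reach

    # true reach-day field with optional multiplicative noise
    truth = {}
    for gas_name, fnoise in (
        ("CH4", scenario.field_noise_ch4),
        ("CO2", scenario.field_noise_co2),
    ):
        g = out["temporal"][gas_name]
        base = np.outer(g.to_numpy(), s_reach[gas_name].to_numpy())
        if not scenario.zero_noise and fnoise > 0:
            base = base * np.exp(
                rng.normal(0, fnoise, base.shape) - fnoise**2 / 2
            )
        truth[gas_name] = pd.DataFrame(
            base, index=cal, columns=s_reach[gas_name].index
        )
    out["true_field"] = truth

    # surveys: all 20 points on n_surveys dates in year 2
    survey_year = cal[cal.year == cal.year.max()]
    surveys = {}
    for gas_name, n_surv, sv_sd in (
        ("CH4", scenario.n_surveys_ch4, scenario.survey_noise_ch4),
        ("CO2", scenario.n_surveys_co2, scenario.survey_noise_co2),
    ):
        dates = survey_year[
            np.linspace(120, 290, n_surv).round().astype(int)
        ]
        rows = []
        for d in dates:
            g_val = out["temporal"][gas_name].loc[d]
            for j, rec in enumerate(points.itertuples(index=False)):
                noise = (
                    1.0
                    if scenario.zero_noise
                    else float(np.exp(rng.normal(0, sv_sd)))
                )
                rows.append(
                    {
                        "point_id": rec.point_id,
                        "branch_id": rec.branch_id,
                        "distance_m": rec.distance_m,
                        "date": d,
                        "gas": gas_name,
                        "conc_uM": spatial[gas_name][j] * g_val * noise,
                    }
                )
        surveys[gas_name] = pd.DataFrame(rows)
    out["surveys"] = surveys

    anchors = points[points["is_anchor"]].reset_index(drop=True)
    anchors = anchors.rename(columns={"point_id": "anchor_id"})[
        ["anchor_id", "branch_id", "distance_m"]
    ]
    out["anchors"] = anchors
    a_idx = points.index[points["is_anchor"]].to_numpy()

    # CH4 anchor bottle samples at the biweekly knots
    rows = []
    for d in knots:
        g_val = g_ch4.loc[d]
        for j, rec in zip(a_idx, anchors.itertuples(index=False)):
            rows.append(
                {
                    "anchor_id": rec.anchor_id,
                    "date": d,
                    "conc": spatial["CH4"][j] * g_val,
                }
            )
    out["anchor_ch4"] = pd.DataFrame(rows)

    # CO2 hourly sensor series per anchor (ppm-free: already uM here;
    # conversion is exercised at the io boundary)
    sensors = {}
    hours = pd.date_range(cal[0], cal[-1] + pd.Timedelta("23h"), freq="h")
    day_of = hours.normalize()
    g_on_hours = g_co2.reindex(day_of).to_numpy()
    for j, rec in zip(a_idx, anchors.itertuples(index=False)):
        base = spatial["CO2"][j] * g_on_hours
        if not scenario.zero_noise:
            diel = 1.0 + scenario.sensor_diel_amp * np.sin(
                2 * np.pi * (hours.hour.to_numpy() - 16) / 24
            )
            base = base * diel
            spikes = rng.random(len(hours)) < scenario.sensor_spike_prob
            base = np.where(spikes, base * rng.uniform(1.4, 2.5, len(hours)), base)
        sensors[rec.anchor_id] = pd.Series(base, index=hours, name="conc_uM")
    out["co2_sensors"] = sensors
    return out


# ---------------------------------------------------------------------------
# tracer injections


def simulate_injection(
    reach: tracer.InjectionReach,
    true_k600: float,
    temp: float,
    gw_fraction: float,
    velocity: float,
    q_mean: float,
    c_up: float = 100.0,
    max_loss_fraction: float | None = None,
) -> tracer.InjectionRun:
    """Forward-model one propane injection with known true k600.

    The downstream concentration follows first-order degassing plus
    lateral dilution, c_down = c_up exp(-rate tau) (q_up/q_down).  When
    the implied tracer loss would exceed `max_loss_fraction`, the
    sampled sub-reach is shortened (as a field crew would move the
    downstream station up) keeping the velocity unchanged.
    """
    sc = gases.schmidt_number(gases.PROPANE, temp)
    k_prop = gases.k_gas_from_k600(true_k600, sc)
    rate = k_prop / (1440.0 * reach.mean_depth)  # min-1
    travel_time = reach.length / (60.0 * velocity)
    length = reach.length
    if max_loss_fraction is not None and rate > 0:
        max_rt = -math.log(1.0 - max_loss_fraction)
        if rate * travel_time > max_rt:
            scale = max_rt / (rate * travel_time)
            travel_time *= scale
            length *= scale
    run_reach = tracer.InjectionReach(
        reach_id=reach.reach_id,
        length=length,
        mean_width=reach.mean_width,
        mean_depth=reach.mean_depth,
        surface_area=length * reach.mean_width,
        slope=reach.slope,
    )
    q_up, q_down = tracer.split_discharge(q_mean, gw_fraction)
    c_down = c_up * math.exp(-rate * travel_time) * (q_up / q_down)
    return tracer.InjectionRun(
        reach=run_reach,
        travel_time=travel_time,
        c_up=c_up,
        c_down=c_down,
        q_up=q_up,
        q_down=q_down,
        water_temp=temp,
    )


#: Injection-reach geometries spanning flat ditches and steep cascades.
_INJECTION_REACHES = (
    ("A", 34.0, 1.0, 0.15, 1.5),
    ("B", 32.0, 1.5, 0.25, 7.5),
    ("C", 54.0, 0.8, 0.15, 7.6),
    ("D", 31.0, 0.5, 0.2, 0.5),
    ("E", 20.0, 1.0, 0.25, 0.3),
    ("F", 24.0, 0.7, 0.1, 19.3),
)


def gen_injection_study(
    scenario: CatchmentScenario,
    water_temp: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the tracer campaign; returns (injections, truth).

    `injections` is the CSV-dialect observation table consumed by
    `tracer.k600_table` (one row per downstream sampling replicate);
    `truth` carries the generating velocity and k600 per observation.
    The generating laws are the published regression surfaces with
    log10-scale noise at the published mean squared errors, so fitting
    the models to the simulated campaign recovers them.
    """
    rng = scenario.rng(5)
    reaches = [
        tracer.InjectionReach(
            reach_id=r,
            length=L,
            mean_width=w,
            mean_depth=d,
            surface_area=L * w,
            slope=s,
        )
        for (r, L, w, d, s) in _INJECTION_REACHES
    ]
    cal = _calendar(scenario)
    season = cal[(cal.month >= 4) & (cal.month <= 11)]
    if water_temp is not None:
        temp_lookup = water_temp.set_index("date")["temp_C"]
    else:
        temp_lookup = None

    inj_rows, truth_rows = [], []
    occ = 0
    while occ < scenario.n_occasions:
        reach = reaches[occ % len(reaches)]
        date = season[int(rng.integers(0, len(season)))]
        if temp_lookup is not None:
            temp = float(temp_lookup.loc[date])
        else:
            temp = float(rng.uniform(5.0, 16.0))
        temp = min(max(temp, 2.0), 18.0)
        # occasion discharge spans the observed range per reach size
        q_mean = float(np.exp(rng.uniform(np.log(4.5), np.log(120.0))))
        v_noise = 10.0 ** rng.normal(0, _maybe(scenario, scenario.velocity_log10_sd))
        velocity = float(
            net.predict_velocity(
                q_mean, reach.slope, bias_correct=False
            )
            * v_noise
        )
        velocity = min(velocity, 0.95)
        n_obs = scenario.n_obs_per_occasion if occ % 3 else scenario.n_obs_per_occasion - 1
        for _ in range(n_obs):
            k_noise = 10.0 ** rng.normal(0, _maybe(scenario, scenario.k600_log10_sd))
            # truncate to the measured k600 envelope the campaign emulates
            true_k600 = float(
                np.clip(
                    net.predict_k600(
                        velocity,
                        reach.slope,
                        calibration=1.0,
                        bias_correct=False,
                        v_cap=np.inf,
                    )
                    * k_noise,
                    0.2,
                    558.7,
                )
            )
            run = simulate_injection(
                reach,
                true_k600,
                temp,
                scenario.gw_fraction,
                velocity,
                q_mean,
                max_loss_fraction=scenario.max_loss_fraction,
            )
            inj_rows.append(
                {
                    "reach_id": reach.reach_id,
                    "date": date,
                    "length_m": run.reach.length,
                    "width_m": run.reach.mean_width,
                    "depth_m": run.reach.mean_depth,
                    "slope_pct": reach.slope,
                    "travel_time_min": run.travel_time,
                    "c_up": run.c_up,
                    "c_down": run.c_down,
                    "q_mean_Ls": q_mean,
                    "q_diff_pct": scenario.gw_fraction * 100.0,
                    "water_temp_C": temp,
                }
            )
            truth_rows.append(
                {
                    "reach_id": reach.reach_id,
                    "date": date,
                    "true_velocity_ms": velocity,
                    "true_k600_md": true_k600,
                }
            )
        occ += 1
    return pd.DataFrame(inj_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# full catchment bundle and generator truth


def generate_catchment(scenario: CatchmentScenario) -> CatchmentInputs:
    """Generate the complete input bundle for the upscaling pipeline."""
    network, reaches = gen_network(scenario)
    stations, true_b, station_locs = gen_discharge(scenario, network)
    air_temp, water_temp = gen_temperatures(scenario)
    conc = gen_concentrations(scenario, network, reaches)
    injections, inj_truth = gen_injection_study(scenario, water_temp)
    return CatchmentInputs(
        profile=network.profile,
        topology=network.topology,
        stations=stations,
        station_locations=station_locs,
        injections=injections,
        surveys={g: conc["surveys"][g] for g in ("CH4", "CO2")},
        anchors=conc["anchors"],
        anchor_ch4=conc["anchor_ch4"],
        co2_sensors=conc["co2_sensors"],
        air_temp=air_temp,
        water_temp=water_temp,
        truth={
            "b": true_b,
            "reaches": reaches,
            "concentrations": conc["true_field"],
            "injections": inj_truth,
            "spatial_points": conc["spatial_points"],
            "spatial_reaches": conc["spatial_reaches"],
            "points": conc["points"],
        },
    )


def true_reach_day_table(
    scenario: CatchmentScenario, inputs: CatchmentInputs
) -> pd.DataFrame:
    """Generator-true reach-day state table (independent of the pipeline).

    Rebuilds discharge, velocity, capped k600, concentrations and
    fluxes from the generator's own truth with its own simple loops
    (running-max velocity cap, brute-force ice-run scan), using only
    the gas-physics kernel from the package.
    """
    reaches = inputs.truth["reaches"]
    b = inputs.truth["b"]
    cal = b.index
    water = inputs.water_temp.set_index("date")["temp_C"].reindex(cal)
    air = inputs.air_temp.set_index("date")["temp_C"].reindex(cal).to_numpy()

    # brute-force ice mask: runs of >3 consecutive sub-zero days
    excluded = np.zeros(len(cal), dtype=bool)
    i = 0
    while i < len(cal):
        if air[i] < 0:
            j = i
            while j < len(cal) and air[j] < 0:
                j += 1
            if j - i > 3:
                excluded[i:j] = True
            i = j
        else:
            i += 1

    frames = []
    for rec in reaches.itertuples(index=False):
        d = b.to_numpy() * rec.drainage_km2
        v = net.predict_velocity(d, rec.slope_pct, bias_correct=False)
        # running-max velocity cap, written out longhand
        k600 = np.empty(len(cal))
        running = -np.inf
        k_at_cap = net.predict_k600(
            0.7, rec.slope_pct, calibration=1.0, bias_correct=False, v_cap=np.inf
        )
        for i, vi in enumerate(v):
            if vi <= 0.7:
                k600[i] = net.predict_k600(
                    vi, rec.slope_pct, calibration=1.0, bias_correct=False,
                    v_cap=np.inf,
                )
                running = max(running, k600[i])
            else:
                k600[i] = running if np.isfinite(running) else k_at_cap
        row = {
            "reach_id": rec.reach_id,
            "date": cal,
            "discharge_Ls": d,
            "velocity_ms": v,
            "k600_md": k600,
            "water_temp_C": water.to_numpy(),
            "area_m2": rec.area_m2,
            "slope_category": rec.slope_category,
            "excluded": excluded,
        }
        df = pd.DataFrame(row)
        for gas_name, mass_col, div in (
            ("CH4", "mass_CH4_kg", 1e6),
            ("CO2", "mass_CO2_Mg", 1e9),
        ):
            gas = gases.GASES[gas_name]
            conc = (
                inputs.truth["concentrations"][gas_name][rec.reach_id]
                .reindex(cal)
                .to_numpy()
            )
            sc = np.array([gases.schmidt_number(gas, t) for t in water.to_numpy()])
            k_gas = k600 * (sc / 600.0) ** -0.5
            c_eq = np.array(
                [
                    gas.solubility(t) * {"CH4": 2.0, "CO2": 405.0}[gas_name] * 1e-6 * 1e6
                    for t in water.to_numpy()
                ]
            )
            flux = k_gas * (conc - c_eq)
            df[f"conc_{gas_name}_uM"] = conc
            df[f"flux_{gas_name}"] = flux
            df[mass_col] = flux * rec.area_m2 * gas.molar_mass / div
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
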