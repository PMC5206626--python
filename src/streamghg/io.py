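"""CSV readers and writers for the pipeline's tabular interfaces.

All files are plain UTF-8 CSV with a header row, ISO dates and decimal
points (see FORMATS.md at the repository root).  Readers validate the
schema and raise `SchemaError` naming the file and the missing columns;
writers round-trip through the matching reader with value equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "CatchmentInputs",
    "read_profile",
    "read_topology",
    "read_stations",
    "read_injections",
    "read_surveys",
    "read_anchor_series",
    "read_sensor_series",
    "read_temperature",
    "read_reaches",
    "write_inputs",
    "read_inputs",
    "write_emissions",
    "write_summary",
]


class SchemaError(ValueError):
    """A tabular file does not match its expected schema."""


SCHEMAS = {
    "profile": ["branch_id", "distance_m", "elevation_m", "drainage_km2", "width_m"],
    "topology": ["branch_id", "downstream_branch_id"],
    "stations": ["station_id", "date", "q_Ls", "drainage_km2"],
    "station_locations": ["station_id", "branch_id", "distance_m"],
    "injections": [
        "reach_id", "date", "length_m", "width_m", "depth_m", "slope_pct",
        "travel_time_min", "c_up", "c_down", "q_mean_Ls", "q_diff_pct",
        "water_temp_C",
    ],
    "surveys": ["point_id", "branch_id", "distance_m", "date", "gas", "conc_uM"],
    "anchors": ["anchor_id", "branch_id", "distance_m"],
    "anchor_series": ["anchor_id", "date", "conc"],
    "sensor": ["anchor_id", "timestamp", "conc_uM"],
    "temperature": ["date", "temp_C"],
    "reaches": [
        "reach_id", "branch_id", "start_m", "end_m", "midpoint_m", "length_m",
        "drop_m", "slope_pct", "slope_category", "drainage_km2", "width_m",
        "area_m2",
    ],
}

_DATE_COLS = {"date"}


def _read_csv(path, kind: str, parse_ts: str | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, FileNotFoundError) as exc:
        raise SchemaError(f"cannot parse {kind} file {path}: {exc}") from exc
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} file {path} is missing columns {missing}; "
            f"found {list(df.columns)}"
        )
    for col in df.columns:
        if col in _DATE_COLS:
            df[col] = pd.to_datetime(df[col])
    if parse_ts and parse_ts in df.columns:
        df[parse_ts] = pd.to_datetime(df[parse_ts])
    return df


def read_profile(path) -> pd.DataFrame:
    return _read_csv(path, "profile")


def read_topology(path) -> dict:
    df = _read_csv(path, "topology")
    out = {}
    for rec in df.itertuples(index=False):
        down = rec.downstream_branch_id
        out[str(rec.branch_id)] = None if pd.isna(down) or down == "" else str(down)
    return out


def read_stations(path) -> pd.DataFrame:
    return _read_csv(path, "stations")


def read_injections(path) -> pd.DataFrame:
    return _read_csv(path, "injections")


def read_surveys(path) -> pd.DataFrame:
    return _read_csv(path, "surveys")


def read_anchor_series(path) -> pd.DataFrame:
    return _read_csv(path, "anchor_series")


def read_sensor_series(path) -> dict[str, pd.Series]:
    """Sensor CSV -> {anchor_id: timestamped Series}."""
    df = _read_csv(path, "sensor", parse_ts="timestamp")
    return {
        aid: grp.set_index("timestamp")["conc_uM"].sort_index()
        for aid, grp in df.groupby("anchor_id")
    }


def read_temperature(path) -> pd.DataFrame:
    return _read_csv(path, "temperature")


def read_reaches(path) -> pd.DataFrame:
    return _read_csv(path, "reaches")


@dataclass
class CatchmentInputs:
    """Everything the upscaling pipeline consumes, in memory.

    `truth` is optional generator ground truth (present for synthetic
    catchments, absent for field data); the pipeline never reads it.
    """

    profile: pd.DataFrame
    topology: dict
    stations: pd.DataFrame
    injections: pd.DataFrame
    surveys: dict  # gas -> survey DataFrame
    anchors: pd.DataFrame
    anchor_ch4: pd.DataFrame
    co2_sensors: dict  # anchor_id -> Series
    air_temp: pd.DataFrame
    water_temp: pd.DataFrame
    station_locations: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def write_inputs(inputs: CatchmentInputs, directory) -> dict[str, Path]:
    """Write an input bundle to CSV files in `directory`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, df):
        p = directory / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    _write("profile", inputs.profile)
    topo = pd.DataFrame(
        [
            {"branch_id": b, "downstream_branch_id": "" if d is None else d}
            for b, d in inputs.topology.items()
        ]
    )
    _write("topology", topo)
    _write("stations", inputs.stations)
    if inputs.station_locations is not None:
        _write("station_locations", inputs.station_locations)
    _write("injections", inputs.injections)
    surveys = pd.concat(
        [inputs.surveys[g] for g in sorted(inputs.surveys)], ignore_index=True
    )
    _write("surveys", surveys)
    _write("anchors", inputs.anchors)
    _write("anchor_ch4", inputs.anchor_ch4)
    sensor_frames = [
        pd.DataFrame(
            {"anchor_id": aid, "timestamp": s.index, "conc_uM": s.to_numpy()}
        )
        for aid, s in sorted(inputs.co2_sensors.items())
    ]
    _write("co2_sensors", pd.concat(sensor_frames, ignore_index=True))
    _write("air_temp", inputs.air_temp)
    _write("water_temp", inputs.water_temp)
    return paths


def read_inputs(directory) -> CatchmentInputs:
    """Read an input bundle written by `write_inputs`."""
    directory = Path(directory)
    surveys = read_surveys(directory / "surveys.csv")
    loc_path = directory / "station_locations.csv"
    sensors_df = _read_csv(directory / "co2_sensors.csv", "sensor", parse_ts="timestamp")
    return CatchmentInputs(
        profile=read_profile(directory / "profile.csv"),
        topology=read_topology(directory / "topology.csv"),
        stations=read_stations(directory / "stations.csv"),
        station_locations=(
            _read_csv(loc_path, "station_locations") if loc_path.exists() else None
        ),
        injections=read_injections(directory / "injections.csv"),
        surveys={g: grp.reset_index(drop=True) for g, grp in surveys.groupby("gas")},
        anchors=_read_csv(directory / "anchors.csv", "anchors"),
        anchor_ch4=read_anchor_series(directory / "anchor_ch4.csv"),
        co2_sensors={
            aid: grp.set_index("timestamp")["conc_uM"].sort_index()
            for aid, grp in sensors_df.groupby("anchor_id")
        },
        air_temp=read_temperature(directory / "air_temp.csv"),
        water_temp=read_temperature(directory / "water_temp.csv"),
    )


def write_emissions(states: pd.DataFrame, path) -> None:
    """Write the long reach-day emission table."""
    states.to_csv(path, index=False)


def write_summary(summary_dict: dict, path) -> None:
    Path(path).write_text(json.dumps(summary_dict, indent=2, default=float))
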