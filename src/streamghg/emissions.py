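"""Reach-day flux integration and network emission summaries.

Combines per-reach-day k600, water temperature and dissolved gas
concentrations into diffusive fluxes (F = k_gas (C_aq - C_eq)) and
per-reach masses, then aggregates to annual network totals with
CV-derived uncertainty bounds, CO2-equivalents, and hot-spot/hot-moment
category tables (slope categories S1-S5 and discharge-ratio bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gases
from .gases import GasSpec, co2_equivalents

__all__ = [
    "reach_day_emission",
    "emission_table",
    "aggregate",
    "uncertainty_bounds",
    "category_ratios",
    "discharge_ratio_bin",
    "mass_balance_flux",
    "EmissionSummary",
    "DISCHARGE_BINS",
]

DISCHARGE_BINS = ("<1", "1-2", "2-3", "3-4", ">4")

#: Atmospheric mixing ratios (ppm) measured during the study period.
DEFAULT_ATM_PPM = {"CH4": 2.0, "CO2": 405.0}


def reach_day_emission(
    area_m2,
    k600,
    temp_c,
    conc_uM,
    atm_ppm: float,
    gas: GasSpec,
) -> pd.DataFrame:
    """Flux and mass for reach-days of one gas (vectorised).

    k600 is converted to the gas- and temperature-specific transfer
    velocity, the Henry's-law equilibrium concentration is subtracted
    from the observed concentration, and the resulting areal flux
    (mmol m-2 d-1) is integrated over the reach surface area into a
    daily mass (kg d-1).
    """
    area_m2 = np.atleast_1d(np.asarray(area_m2, dtype=float))
    k600 = np.atleast_1d(np.asarray(k600, dtype=float))
    temp_c = np.atleast_1d(np.asarray(temp_c, dtype=float))
    conc_uM = np.atleast_1d(np.asarray(conc_uM, dtype=float))
    sc = np.array([gases.schmidt_number(gas, t) for t in temp_c])
    k_gas = k600 * (sc / 600.0) ** -0.5
    c_eq = np.array(
        [gases.equilibrium_concentration(atm_ppm, t, gas) for t in temp_c]
    )
    flux = k_gas * (conc_uM - c_eq)  # mmol m-2 d-1
    mass_kg = flux * area_m2 * gas.molar_mass / 1e6
    return pd.DataFrame(
        {
            "k_gas_md": k_gas,
            "c_eq_uM": c_eq,
            "flux_mmol_m2_d": flux,
            "mass_kg_d": mass_kg,
        }
    )


def emission_table(
    reaches: pd.DataFrame,
    discharge: pd.DataFrame,
    velocity: pd.DataFrame,
    k600: pd.DataFrame,
    water_temp: pd.DataFrame,
    conc: dict[str, pd.DataFrame],
    excluded: pd.Series | None = None,
    missing: dict[str, pd.DataFrame] | None = None,
    atm_ppm: dict[str, float] = DEFAULT_ATM_PPM,
) -> pd.DataFrame:
    """Build the long reach-day state table.

    All wide inputs are indexed by date with one column per reach_id;
    `conc` maps gas name ("CH4", "CO2") to such a frame.  `excluded`
    is the boolean ice mask on the date index; `missing` flags
    reach-days whose concentration is an edge extrapolation.  Excluded
    and missing reach-days are retained in the table with an
    ``excluded`` flag so downstream aggregation can drop them while the
    exclusion fraction stays reportable.
    """
    areas = reaches.set_index("reach_id")["area_m2"]
    cats = reaches.set_index("reach_id")["slope_category"]
    frames = []
    for reach_id in k600.columns:
        n = len(k600.index)
        df = pd.DataFrame(
            {
                "reach_id": reach_id,
                "date": k600.index,
                "discharge_Ls": discharge[reach_id].to_numpy(),
                "velocity_ms": velocity[reach_id].to_numpy(),
                "k600_md": k600[reach_id].to_numpy(),
                "water_temp_C": water_temp[reach_id].to_numpy(),
                "area_m2": areas.loc[reach_id],
                "slope_category": cats.loc[reach_id],
            }
        )
        excl = (
            excluded.to_numpy()
            if excluded is not None
            else np.zeros(n, dtype=bool)
        )
        for gas_name in ("CH4", "CO2"):
            gas = gases.GASES[gas_name]
            parts = reach_day_emission(
                df["area_m2"].to_numpy(),
                df["k600_md"].to_numpy(),
                df["water_temp_C"].to_numpy(),
                conc[gas_name][reach_id].to_numpy(),
                atm_ppm[gas_name],
                gas,
            )
            df[f"conc_{gas_name}_uM"] = conc[gas_name][reach_id].to_numpy()
            df[f"flux_{gas_name}"] = parts["flux_mmol_m2_d"].to_numpy()
            if gas_name == "CH4":
                df["mass_CH4_kg"] = parts["mass_kg_d"].to_numpy()
            else:
                df["mass_CO2_Mg"] = parts["mass_kg_d"].to_numpy() / 1e3
            if missing is not None and gas_name in missing:
                excl = excl | missing[gas_name][reach_id].to_numpy()
            # no concentration even after gap-filling -> excluded
            excl = excl | np.isnan(conc[gas_name][reach_id].to_numpy())
        df["excluded"] = excl
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def uncertainty_bounds(mean: float, pct: float) -> tuple[float, float]:
    """Symmetric relative uncertainty bounds (mean*(1-p), mean*(1+p))."""
    frac = pct / 100.0
    return mean * (1.0 - frac), mean * (1.0 + frac)


@dataclass
class EmissionSummary:
    """Network emission totals, bounds and category ratio tables."""

    annual_totals: pd.DataFrame  # index year; columns CH4_kg, CO2_Mg
    mean_annual_ch4_kg: float
    mean_annual_co2_Mg: float
    ch4_bounds_kg: tuple[float, float]
    co2_bounds_Mg: tuple[float, float]
    mean_flux_ch4: float  # mmol m-2 d-1 over included reach-days
    mean_flux_co2: float
    flux_bounds_ch4: tuple[float, float]
    flux_bounds_co2: tuple[float, float]
    co2_eq_Mg: float
    co2_eq_bounds_Mg: tuple[float, float]
    ch4_share_pct: float
    slope_ratios: pd.DataFrame
    discharge_ratios: pd.DataFrame
    excluded_fraction: float
    uncertainty_pct: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "annual_totals": {
                str(y): {
                    "CH4_kg": float(r["CH4_kg"]),
                    "CO2_Mg": float(r["CO2_Mg"]),
                }
                for y, r in self.annual_totals.iterrows()
            },
            "mean_annual_CH4_kg": self.mean_annual_ch4_kg,
            "mean_annual_CO2_Mg": self.mean_annual_co2_Mg,
            "CH4_bounds_kg": list(self.ch4_bounds_kg),
            "CO2_bounds_Mg": list(self.co2_bounds_Mg),
            "mean_flux_CH4_mmol_m2_d": self.mean_flux_ch4,
            "mean_flux_CO2_mmol_m2_d": self.mean_flux_co2,
            "flux_bounds_CH4": list(self.flux_bounds_ch4),
            "flux_bounds_CO2": list(self.flux_bounds_co2),
            "CO2_eq_Mg": self.co2_eq_Mg,
            "CO2_eq_bounds_Mg": list(self.co2_eq_bounds_Mg),
            "CH4_share_pct": self.ch4_share_pct,
            "excluded_fraction": self.excluded_fraction,
            "uncertainty_pct": self.uncertainty_pct,
            "slope_ratios": self.slope_ratios.reset_index().to_dict("records"),
            "discharge_ratios": self.discharge_ratios.reset_index().to_dict(
                "records"
            ),
        }


def aggregate(
    states: pd.DataFrame,
    ch4_uncertainty_pct: float = 60.0,
    co2_uncertainty_pct: float = 25.0,
    gwp: float = 28.0,
) -> EmissionSummary:
    """Aggregate the reach-day table into an `EmissionSummary`.

    Excluded reach-days (ice mask / missing concentration) are dropped
    from sums and means but counted in the exclusion fraction.  Annual
    totals are per calendar year; the headline totals are the mean
    annual values across the years present.
    """
    excluded_fraction = float(states["excluded"].mean()) if len(states) else 0.0
    ok = states.loc[~states["excluded"]].copy()
    ok["year"] = pd.to_datetime(ok["date"]).dt.year
    annual = ok.groupby("year").agg(
        CH4_kg=("mass_CH4_kg", "sum"), CO2_Mg=("mass_CO2_Mg", "sum")
    )
    ch4_total = float(annual["CH4_kg"].mean())
    co2_total = float(annual["CO2_Mg"].mean())
    mean_flux_ch4 = float(ok["flux_CH4"].mean())
    mean_flux_co2 = float(ok["flux_CO2"].mean())
    co2_eq, share = co2_equivalents(ch4_total, co2_total, gwp)
    eq_low, _ = co2_equivalents(
        uncertainty_bounds(ch4_total, ch4_uncertainty_pct)[0],
        uncertainty_bounds(co2_total, co2_uncertainty_pct)[0],
        gwp,
    )
    eq_high, _ = co2_equivalents(
        uncertainty_bounds(ch4_total, ch4_uncertainty_pct)[1],
        uncertainty_bounds(co2_total, co2_uncertainty_pct)[1],
        gwp,
    )
    return EmissionSummary(
        annual_totals=annual,
        mean_annual_ch4_kg=ch4_total,
        mean_annual_co2_Mg=co2_total,
        ch4_bounds_kg=uncertainty_bounds(ch4_total, ch4_uncertainty_pct),
        co2_bounds_Mg=uncertainty_bounds(co2_total, co2_uncertainty_pct),
        mean_flux_ch4=mean_flux_ch4,
        mean_flux_co2=mean_flux_co2,
        flux_bounds_ch4=uncertainty_bounds(mean_flux_ch4, ch4_uncertainty_pct),
        flux_bounds_co2=uncertainty_bounds(mean_flux_co2, co2_uncertainty_pct),
        co2_eq_Mg=co2_eq,
        co2_eq_bounds_Mg=(eq_low, eq_high),
        ch4_share_pct=share,
        slope_ratios=category_ratios(ok, "slope_category"),
        discharge_ratios=category_ratios(ok, "discharge_bin"),
        excluded_fraction=excluded_fraction,
        uncertainty_pct={"CH4": ch4_uncertainty_pct, "CO2": co2_uncertainty_pct},
    )


def discharge_ratio_bin(reach_day_q, reach_mean_q):
    """Bin reach-day discharge by its ratio to the reach mean.

    Ratios at or below 1 fall in the first bin (most days sit at or
    below the mean); the remaining bins are lower-inclusive.
    """
    ratio = np.asarray(reach_day_q, dtype=float) / np.asarray(
        reach_mean_q, dtype=float
    )
    # first bin takes everything at or below the mean; the rest are
    # lower-inclusive: (1,2), [2,3), [3,4), [4, inf)
    idx = np.where(ratio <= 1.0, 0, np.digitize(ratio, (2.0, 3.0, 4.0)) + 1)
    labels = np.array(DISCHARGE_BINS)[idx]
    return labels if labels.ndim else str(labels)


def category_ratios(states: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Hot-spot/hot-moment table: category means relative to overall means.

    `grouping` is ``"slope_category"`` (adds percent stream area) or
    ``"discharge_bin"`` (adds percent occurrence of reach-days; bins are
    computed from each reach's mean discharge over the table if not
    already present).
    """
    states = states.copy()
    if grouping == "discharge_bin" and "discharge_bin" not in states:
        mean_q = states.groupby("reach_id")["discharge_Ls"].transform("mean")
        states["discharge_bin"] = discharge_ratio_bin(
            states["discharge_Ls"].to_numpy(), mean_q.to_numpy()
        )
    overall = {
        "CH4": states["flux_CH4"].mean(),
        "CO2": states["flux_CO2"].mean(),
        "k": states["k600_md"].mean(),
    }
    grp = states.groupby(grouping)
    table = pd.DataFrame(
        {
            "CH4_emission_ratio": grp["flux_CH4"].mean() / overall["CH4"],
            "CO2_emission_ratio": grp["flux_CO2"].mean() / overall["CO2"],
            "k_ratio": grp["k600_md"].mean() / overall["k"],
        }
    )
    if grouping == "slope_category":
        reach_areas = states.drop_duplicates("reach_id").set_index("reach_id")
        area_by_cat = reach_areas.groupby("slope_category")["area_m2"].sum()
        table.insert(0, "percent_area", 100.0 * area_by_cat / area_by_cat.sum())
        order = [c for c in ("S1", "S2", "S3", "S4", "S5") if c in table.index]
    else:
        table.insert(
            0, "percent_occurrence", 100.0 * grp.size() / len(states)
        )
        order = [c for c in DISCHARGE_BINS if c in table.index]
    return table.loc[order]


def mass_balance_flux(q_Ls: float, c_up_uM: float, c_down_uM: float, area_m2: float):
    """Areal flux (mmol m-2 d-1) from an up/downstream mass balance.

    F = Q * 86.4 * (C_up - C_down) / A; the 86.4 converts
    L s-1 * umol L-1 into mmol d-1.  Used to validate k-based fluxes
    over steep, strongly degassing sections.
    """
    if np.any(np.asarray(area_m2) <= 0):
        raise ValueError("area must be positive")
    return (
        np.asarray(q_Ls, dtype=float)
        * 86.4
        * (np.asarray(c_up_uM, dtype=float) - np.asarray(c_down_uM, dtype=float))
        / np.asarray(area_m2, dtype=float)
    )
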