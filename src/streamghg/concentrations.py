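"""Reconstruction of reach-level dissolved gas concentrations.

Dissolved CH4 and CO2 are sampled sparsely in space (survey campaigns
over ~20 network points) but densely in time at a few anchor stations
(biweekly bottle samples for CH4, high-frequency sensors averaged to
daily means for CO2).  The reconstruction assumes the field is
separable: a static spatial pattern (per-reach ratio to the nearest
anchor) times the anchor's time series.  Ratios come from linearly
interpolating each survey along the channel network; their per-reach
coefficient of variation across surveys drives the emission uncertainty
bounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "despike_sensor",
    "daily_means",
    "spatial_interpolate",
    "assign_anchors",
    "relative_ratios",
    "fill_anchor_daily",
    "temporal_reconstruct",
    "uncertainty_pct",
]


# ---------------------------------------------------------------------------
# sensor cleaning


def despike_sensor(
    series: pd.Series, threshold: float = 0.2, window: str = "12h"
) -> pd.Series:
    """Remove condensation spikes from a sensor series.

    A value is removed when it deviates by more than `threshold`
    (relative) from the mean of the 12 h window before it AND from the
    mean of the 12 h window after it; at the ends of the series the
    single available window decides.  The point itself is excluded from
    its windows.  Empty input returns empty output.
    """
    if series.empty:
        return series.copy()
    if not series.index.is_monotonic_increasing or series.index.has_duplicates:
        raise ValueError("sensor timestamps must be strictly increasing")
    t = series.index.view("int64")
    v = series.to_numpy(dtype=float)
    w = int(pd.Timedelta(window).value)
    csum = np.concatenate(([0.0], np.cumsum(v)))

    lo = np.searchsorted(t, t - w, side="left")  # first index in (t-w, t]... see below
    hi = np.searchsorted(t, t + w, side="right")  # one past last index in [t, t+w)
    idx = np.arange(v.size)
    # before-window (t-w, t): indices [lo, i); after-window (t, t+w]: (i, hi)
    n_before = idx - lo
    sum_before = csum[idx] - csum[lo]
    n_after = hi - idx - 1
    sum_after = csum[hi] - csum[idx + 1]

    def deviates(total, count):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
            return np.where(
                count > 0, np.abs(v - mean) > threshold * np.abs(mean), np.nan
            )

    dev_b = deviates(sum_before, n_before)
    dev_a = deviates(sum_after, n_after)
    both = np.stack([dev_b, dev_a])
    # spike iff it deviates on every side that has data; keep isolated points
    has_any = ~np.all(np.isnan(both), axis=0)
    remove = has_any & np.all(np.nan_to_num(both, nan=1.0) > 0, axis=0)
    return series[~remove]


def daily_means(series: pd.Series) -> pd.Series:
    """Daily mean of a (cleaned) sensor series, indexed by date."""
    out = series.groupby(series.index.normalize()).mean()
    out.index.name = "date"
    return out


# ---------------------------------------------------------------------------
# spatial interpolation


def spatial_interpolate(
    survey: pd.DataFrame, network: Network, reaches: pd.DataFrame
) -> pd.Series:
    """Interpolate one survey's samples to every reach midpoint.

    `survey` has columns ``branch_id, distance_m, conc``.  Within a
    branch the concentration varies linearly with along-channel distance
    between samples and is held constant beyond the terminal ones.  At a
    confluence the downstream branch starts from the drainage-area
    (i.e. discharge, since D = bA) weighted mean of the merging
    branches' endpoint values.  Branches without samples inherit the
    value at their junction from the branch they drain into.

    Returns a Series of concentrations indexed by reach_id.
    """
    if survey.empty:
        raise ValueError("survey has no samples")
    tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def mouth_area(branch: str) -> float:
        prof = network.profile[network.profile["branch_id"] == branch]
        return float(prof.loc[prof["distance_m"].idxmax(), "drainage_km2"])

    for branch in network.topological_order():
        rows = survey[survey["branch_id"] == branch].sort_values("distance_m")
        xs = rows["distance_m"].to_numpy(dtype=float)
        cs = rows["conc"].to_numpy(dtype=float)
        parents = [p for p in network.parents_of(branch) if p in tables]
        if parents:
            # virtual sample at the branch head: discharge-weighted mean
            # of the merging branches' most-downstream values
            vals, weights = [], []
            for p in parents:
                pxs, pcs = tables[p]
                vals.append(float(np.interp(network.branch_length(p), pxs, pcs)))
                weights.append(mouth_area(p))
            head_val = float(np.average(vals, weights=weights))
            if xs.size == 0 or xs[0] > 0:
                xs = np.concatenate(([0.0], xs))
                cs = np.concatenate(([head_val], cs))
        if xs.size:
            tables[branch] = (xs, cs)

    # second pass, outlet -> headwaters: sample-less branches take the
    # value where they join their downstream branch (its head)
    for branch in reversed(network.topological_order()):
        if branch in tables:
            continue
        child = network.topology[branch]
        if child is None or child not in tables:
            raise ValueError(f"no samples reachable for branch {branch}")
        cxs, ccs = tables[child]
        tables[branch] = (np.array([0.0]), np.array([np.interp(0.0, cxs, ccs)]))

    out = {}
    for rec in reaches.itertuples(index=False):
        xs, cs = tables[rec.branch_id]
        out[rec.reach_id] = float(np.interp(rec.midpoint_m, xs, cs))
    return pd.Series(out, name="conc").rename_axis("reach_id")


def assign_anchors(
    reaches: pd.DataFrame, anchors: pd.DataFrame, network: Network
) -> pd.Series:
    """Map each reach to its nearest anchor station along the network.

    `anchors` has columns ``anchor_id, branch_id, distance_m``.
    Returns a Series reach_id -> anchor_id.
    """
    out = {}
    for rec in reaches.itertuples(index=False):
        best, best_d = None, np.inf
        for a in anchors.itertuples(index=False):
            d = network.path_distance(
                rec.branch_id, rec.midpoint_m, a.branch_id, a.distance_m
            )
            if d < best_d:
                best, best_d = a.anchor_id, d
        out[rec.reach_id] = best
    return pd.Series(out, name="anchor_id").rename_axis("reach_id")


# ---------------------------------------------------------------------------
# ratios and temporal reconstruction


def relative_ratios(
    interpolated: pd.DataFrame,
    anchor_conc: pd.DataFrame,
    assignment: pd.Series,
) -> pd.DataFrame:
    """Per-reach concentration ratios to the assigned anchor.

    Parameters
    ----------
    interpolated : DataFrame
        One column per survey date, one row per reach (output of
        `spatial_interpolate` stacked over surveys).
    anchor_conc : DataFrame
        Anchor concentrations with the same survey-date columns, one
        row per anchor_id.
    assignment : Series
        reach_id -> anchor_id.

    Returns a DataFrame indexed by reach_id with columns ``ratio``
    (mean over surveys), ``cv`` (sd/mean over surveys, 0 for a single
    survey) and ``n_surveys``.
    """
    rows = {}
    for reach_id, row in interpolated.iterrows():
        anchor = assignment.loc[reach_id]
        ratios = (row / anchor_conc.loc[anchor]).dropna()
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
        rows[reach_id] = {
            "ratio": mean,
            "cv": sd / mean if mean != 0 else 0.0,
            "n_surveys": int(len(ratios)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("reach_id")


def fill_anchor_daily(
    anchor_series: pd.DataFrame, calendar: pd.DatetimeIndex
) -> tuple[dict, dict]:
    """Gap-fill each anchor's series to daily resolution.

    Linear interpolation in time between sampled days; days outside the
    sampled span carry the nearest value and are flagged.  Returns
    ``({anchor_id: Series}, {anchor_id: edge_flag Series})``.
    """
    filled, edge = {}, {}
    for anchor_id, grp in anchor_series.groupby("anchor_id"):
        s = grp.set_index("date")["conc"].sort_index()
        s = s[~s.index.duplicated()]
        on_cal = s.reindex(calendar.union(s.index)).interpolate(method="time")
        before = calendar < s.index.min()
        after = calendar > s.index.max()
        on_cal = on_cal.ffill().bfill()
        filled[anchor_id] = on_cal.reindex(calendar)
        edge[anchor_id] = pd.Series(before | after, index=calendar)
    return filled, edge


def temporal_reconstruct(
    anchor_series: pd.DataFrame,
    ratios: pd.DataFrame,
    assignment: pd.Series,
    calendar: pd.DatetimeIndex,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct daily per-reach concentrations.

    Anchor gaps between sampled days are filled by linear interpolation
    in time; days before the first or after the last sample carry the
    nearest value and are flagged.  Each reach's series is its ratio
    times its assigned anchor's gap-filled series.

    Parameters
    ----------
    anchor_series : DataFrame
        Columns ``date, anchor_id, conc`` (sparse or daily).
    ratios, assignment
        From `relative_ratios` / `assign_anchors`.
    calendar : DatetimeIndex
        Daily index to reconstruct on.

    Returns
    -------
    (conc, edge_flag)
        Two DataFrames indexed by `calendar` with one column per reach:
        concentrations (uM) and a boolean edge-extrapolation flag.
    """
    filled, edge = fill_anchor_daily(anchor_series, calendar)
    conc = pd.DataFrame(
        {
            reach_id: ratios.loc[reach_id, "ratio"] * filled[assignment.loc[reach_id]]
            for reach_id in ratios.index
        },
        index=calendar,
    )
    flags = pd.DataFrame(
        {reach_id: edge[assignment.loc[reach_id]] for reach_id in ratios.index},
        index=calendar,
    )
    conc.index.name = flags.index.name = "date"
    return conc, flags


def uncertainty_pct(ratio_cvs) -> float:
    """Network-wide uncertainty (%): 100 x the maximum per-reach ratio CV."""
    cvs = np.asarray(ratio_cvs, dtype=float)
    if cvs.size == 0:
        return 0.0
    return float(100.0 * np.nanmax(cvs))
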