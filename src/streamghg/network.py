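"""Stream-network discretisation, discharge scaling and k600 prediction.

The channel network is a tree of branches; each branch drains into the
head (local distance 0) of its parent branch, and the root branch ends
at the catchment outlet.  A longitudinal profile (distance, elevation,
drainage area, width per branch) is discretised into reaches of fixed
elevation drop, so steep terrain yields short reaches and flat terrain
long ones.

Daily discharge everywhere on the network comes from the one-parameter
drainage-area scaling D = b A fitted through the origin across gauging
stations each day.  Water velocity and k600 for every reach-day are then
predicted with two log10-linear regression models (velocity from
discharge and slope; k600 from velocity and slope), back-transformed
with a smearing bias correction and rescaled by a measured-vs-modelled
calibration factor.  Predictions are only trusted up to a velocity cap;
above it the reach-specific maximum previously modelled k600 is used.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ProfilePoint",
    "Reach",
    "DayScaling",
    "RegressionModel",
    "Network",
    "VELOCITY_MODEL",
    "K600_MODEL",
    "SLOPE_CATEGORIES",
    "discretize",
    "slope_category",
    "fit_daily_scaling",
    "reach_discharge",
    "predict_velocity",
    "predict_k600",
    "predict_k600_series",
    "fit_velocity_model",
    "fit_k600_model",
    "calibration_factor",
    "ice_mask",
]

#: Slope-category boundaries in percent; half-open, lower-inclusive:
#: S1 [0,1), S2 [1,2), S3 [2,4), S4 [4,6), S5 [6, inf).
SLOPE_CATEGORIES = ("S1", "S2", "S3", "S4", "S5")
_SLOPE_EDGES = (1.0, 2.0, 4.0, 6.0)

#: Floor applied to slopes before log10 (flattest reaches have slope ~0).
DEFAULT_SLOPE_FLOOR = 0.05


@dataclass(frozen=True)
class ProfilePoint:
    branch_id: str
    distance: float  # m along branch, increasing downstream
    elevation: float  # m
    drainage_area: float  # km2
    width: float | None = None  # m


@dataclass(frozen=True)
class Reach:
    reach_id: str
    branch_id: str
    length: float  # m
    slope: float  # %
    surface_area: float  # m2
    drainage_area: float  # km2
    slope_category: str
    group_label: str = ""


@dataclass(frozen=True)
class DayScaling:
    """Daily discharge/drainage-area proportionality D = b A."""

    date: object
    b: float  # L s-1 km-2
    r2: float
    n_stations: int


@dataclass(frozen=True)
class RegressionModel:
    """A log10-linear regression model.

    `intercept` and `slopes` act on the model's transformed scales
    (velocity model: log10 D, log10 S; k600 model: V, log10 S); `mse`
    is the residual mean square on the log10 response scale and feeds
    the smearing back-transform correction.
    """

    intercept: float
    slopes: tuple[float, ...]
    mse: float
    adj_r2: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be non-negative")

    def smearing_factor(self) -> float:
        """Multiplicative back-transform bias correction.

        For log10-scale residuals with variance `mse`, the unbiased
        back-transform multiplies 10**prediction by
        exp(mse * ln(10)**2 / 2).
        """
        return math.exp(self.mse * math.log(10.0) ** 2 / 2.0)


#: Published velocity model: log10 V = -1.323 + 0.466 log10 D + 0.056 log10 S.
VELOCITY_MODEL = RegressionModel(
    intercept=-1.323, slopes=(0.466, 0.056), mse=0.006, adj_r2=0.91, n=21
)

#: Published k600 model: log10 k600 = 0.319 + 2.110 V + 1.026 log10 S.
K600_MODEL = RegressionModel(
    intercept=0.319, slopes=(2.110, 1.026), mse=0.050, adj_r2=0.92, n=53
)

DEFAULT_CALIBRATION = 0.89  # measured-vs-modelled rescaling of modelled k600
DEFAULT_V_CAP = 0.7  # m s-1; above this the model is not trusted


# ---------------------------------------------------------------------------
# network topology


@dataclass
class Network:
    """A branched channel network.

    Parameters
    ----------
    profile : DataFrame
        Columns ``branch_id, distance_m, elevation_m, drainage_km2,
        width_m``; distance increases downstream within a branch.
    topology : dict
        ``branch_id -> downstream branch_id`` (the branch's mouth joins
        the head, local distance 0, of its parent); the root/outlet
        branch maps to ``None``.
    """

    profile: pd.DataFrame
    topology: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        branches = set(self.profile["branch_id"].unique())
        for b in branches:
            self.topology.setdefault(b, None)
        roots = [b for b in branches if self.topology.get(b) is None]
        if len(roots) != 1:
            raise ValueError(f"network must have exactly one outlet branch, got {roots}")
        self.root = roots[0]

    def branch_length(self, branch: str) -> float:
        d = self.profile.loc[self.profile["branch_id"] == branch, "distance_m"]
        return float(d.max() - d.min())

    def parents_of(self, branch: str) -> list[str]:
        return sorted(b for b, p in self.topology.items() if p == branch)

    def _chain(self, branch: str) -> list[str]:
        chain = [branch]
        while self.topology[chain[-1]] is not None:
            chain.append(self.topology[chain[-1]])
        return chain

    def topological_order(self) -> list[str]:
        """Branches ordered headwaters -> outlet."""
        return sorted(
            self.topology, key=lambda b: len(self._chain(b)), reverse=True
        )

    def path_distance(
        self, branch_a: str, dist_a: float, branch_b: str, dist_b: float
    ) -> float:
        """Along-channel distance between two network points (m)."""
        if branch_a == branch_b:
            return abs(dist_a - dist_b)
        chain_a, chain_b = self._chain(branch_a), self._chain(branch_b)
        common = next((b for b in chain_a if b in chain_b), None)
        if common is None:
            raise ValueError("points are not on a connected network")

        def downstream_dist(chain: list[str], dist: float) -> float:
            # distance from the point to the head of `common`
            total = self.branch_length(chain[0]) - dist
            for b in chain[1 : chain.index(common)]:
                total += self.branch_length(b)
            return total

        if common == branch_a:
            return downstream_dist(chain_b, dist_b) + dist_a
        if common == branch_b:
            return downstream_dist(chain_a, dist_a) + dist_b
        return downstream_dist(chain_a, dist_a) + downstream_dist(chain_b, dist_b)


# ---------------------------------------------------------------------------
# discretisation


def slope_category(slope_pct: float) -> str:
    """Assign a slope (%) to one of the categories S1-S5 (lower-inclusive)."""
    if slope_pct < 0:
        raise ValueError(f"slope must be non-negative, got {slope_pct}")
    idx = int(np.digitize(slope_pct, _SLOPE_EDGES))
    return SLOPE_CATEGORIES[idx]


def _mean_piecewise_linear(x0: float, x1: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Mean of a piecewise-linear function over [x0, x1]."""
    if x1 <= x0:
        return float(np.interp(x0, xs, ys))
    inner = xs[(xs > x0) & (xs < x1)]
    grid = np.concatenate(([x0], inner, [x1]))
    vals = np.interp(grid, xs, ys)
    return float(np.trapezoid(vals, grid) / (x1 - x0))


def discretize(
    network: Network,
    dz: float = 0.5,
    width_power_law: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Discretise the longitudinal profile into fixed-drop reaches.

    Each reach accumulates `dz` metres of elevation drop (the final
    partial reach of a branch is kept); local elevation rises are
    flattened to zero drop with a logged warning.  Reach width is the
    mean profile width over the reach span (or ``c * A**e`` from
    `width_power_law` when the profile carries no widths) and surface
    area is length x width.

    Returns a DataFrame with one row per reach: reach_id, branch_id,
    start/end local distances, length_m, drop_m, slope_pct,
    slope_category, drainage_km2, width_m, area_m2, midpoint_m.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    out = []
    for branch in network.topological_order():
        prof = (
            network.profile[network.profile["branch_id"] == branch]
            .sort_values("distance_m")
            .reset_index(drop=True)
        )
        dist = prof["distance_m"].to_numpy(dtype=float)
        elev = prof["elevation_m"].to_numpy(dtype=float)
        if len(dist) < 2:
            raise ValueError(f"branch {branch} needs at least two profile points")
        if np.any(np.diff(dist) <= 0):
            raise ValueError(f"profile distances must strictly increase on {branch}")
        drops = -np.diff(elev)
        if np.any(drops < 0):
            logger.warning(
                "branch %s: %d local elevation rise(s) flattened to zero drop",
                branch,
                int(np.sum(drops < 0)),
            )
            drops = np.maximum(drops, 0.0)
        cumdrop = np.concatenate(([0.0], np.cumsum(drops)))
        total_drop = cumdrop[-1]

        # boundary distances at cumulative drops dz, 2dz, ... (< total)
        bounds = [dist[0]]
        n_full = int(math.floor(total_drop / dz + 1e-9))
        for j in range(1, n_full + 1):
            target = j * dz
            if target >= total_drop - 1e-12:
                break
            i = int(np.searchsorted(cumdrop, target, side="left"))
            if cumdrop[i] == target:
                bounds.append(dist[i])
            else:
                seg_drop = cumdrop[i] - cumdrop[i - 1]
                frac = (target - cumdrop[i - 1]) / seg_drop
                bounds.append(dist[i - 1] + frac * (dist[i] - dist[i - 1]))
        bounds.append(dist[-1])

        if width_power_law is None and prof["width_m"].isna().any():
            raise ValueError(
                f"branch {branch} has missing widths and no width power law given"
            )
        widths = prof["width_m"].to_numpy(dtype=float)
        areas_km2 = prof["drainage_km2"].to_numpy(dtype=float)

        for j in range(len(bounds) - 1):
            x0, x1 = bounds[j], bounds[j + 1]
            length = x1 - x0
            drop = float(
                np.interp(x1, dist, cumdrop) - np.interp(x0, dist, cumdrop)
            )
            slope = 100.0 * drop / length if length > 0 else 0.0
            mid = 0.5 * (x0 + x1)
            a_mid = float(np.interp(mid, dist, areas_km2))
            if width_power_law is not None:
                c, e = width_power_law
                width = c * a_mid**e
            else:
                width = _mean_piecewise_linear(x0, x1, dist, widths)
            out.append(
                {
                    "reach_id": f"{branch}-{j:03d}",
                    "branch_id": branch,
                    "start_m": x0,
                    "end_m": x1,
                    "midpoint_m": mid,
                    "length_m": length,
                    "drop_m": drop,
                    "slope_pct": slope,
                    "slope_category": slope_category(slope),
                    "drainage_km2": a_mid,
                    "width_m": width,
                    "area_m2": length * width,
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# discharge scaling


def fit_daily_scaling(
    drainage_km2, discharge_Ls, date=None
) -> DayScaling:
    """Fit the through-origin scaling D = b A for one day.

    `b` is the least-squares slope through the origin; r2 is the
    fraction of variance (about the mean) explained, clipped to [0, 1].
    """
    a = np.asarray(drainage_km2, dtype=float)
    d = np.asarray(discharge_Ls, dtype=float)
    if a.size < 2 or np.unique(a).size < 2:
        raise ValueError("daily scaling needs >= 2 stations with distinct areas")
    b = float(np.sum(a * d) / np.sum(a * a))
    ss_res = float(np.sum((d - b * a) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    return DayScaling(date=date, b=b, r2=r2, n_stations=int(a.size))


def reach_discharge(drainage_km2, scaling: DayScaling):
    """Daily reach discharge D = b A (L s-1)."""
    return scaling.b * np.asarray(drainage_km2, dtype=float)


# ---------------------------------------------------------------------------
# regression models


def _floor_slope(s, slope_floor: float):
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("slope must be non-negative")
    return np.maximum(s, slope_floor)


def predict_velocity(
    d,
    s,
    model: RegressionModel = VELOCITY_MODEL,
    bias_correct: bool = True,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
):
    """Predict water velocity (m s-1) from discharge (L s-1) and slope (%).

    Evaluates the log10-linear velocity model and back-transforms,
    multiplying by the smearing factor unless ``bias_correct=False``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("discharge must be positive")
    s = _floor_slope(s, slope_floor)
    log10v = (
        model.intercept
        + model.slopes[0] * np.log10(d)
        + model.slopes[1] * np.log10(s)
    )
    v = 10.0**log10v
    if bias_correct:
        v = v * model.smearing_factor()
    return v if v.ndim else float(v)


def _k600_uncapped(
    v,
    s,
    model: RegressionModel,
    calibration: float,
    bias_correct: bool,
    slope_floor: float,
):
    v = np.asarray(v, dtype=float)
    s = _floor_slope(s, slope_floor)
    log10k = model.intercept + model.slopes[0] * v + model.slopes[1] * np.log10(s)
    k = 10.0**log10k
    if bias_correct:
        k = k * model.smearing_factor()
    return calibration * k


def predict_k600(
    v: float,
    s: float,
    model: RegressionModel = K600_MODEL,
    calibration: float = DEFAULT_CALIBRATION,
    v_cap: float = DEFAULT_V_CAP,
    reach_max: float | None = None,
    bias_correct: bool = True,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> float:
    """Predict k600 (m d-1) from velocity (m s-1) and slope (%).

    Below the velocity cap the model is evaluated and rescaled by the
    calibration factor; above it the model is not extrapolated and
    `reach_max` (the largest k600 previously modelled for the reach at
    v <= v_cap) is returned instead.  Without a `reach_max` the model
    is evaluated at the cap itself, with a warning.
    """
    if v < 0:
        raise ValueError("velocity must be non-negative")
    if v <= v_cap:
        return float(
            _k600_uncapped(v, s, model, calibration, bias_correct, slope_floor)
        )
    if reach_max is not None:
        return float(reach_max)
    warnings.warn(
        f"velocity {v:.3g} m s-1 above cap {v_cap} with no reach maximum "
        "available; evaluating at the cap",
        stacklevel=2,
    )
    return float(
        _k600_uncapped(v_cap, s, model, calibration, bias_correct, slope_floor)
    )


def predict_k600_series(
    v,
    s: float,
    model: RegressionModel = K600_MODEL,
    calibration: float = DEFAULT_CALIBRATION,
    v_cap: float = DEFAULT_V_CAP,
    bias_correct: bool = True,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """k600 for a time-ordered velocity series of one reach.

    Days with v above the cap receive the running maximum of previously
    modelled (v <= cap) k600 values for this reach; if the cap is hit
    before any in-range day, the model evaluated at the cap is used.
    Returns ``(k600_array, capped_flags)``.
    """
    v = np.asarray(v, dtype=float)
    k_unc = _k600_uncapped(v, s, model, calibration, bias_correct, slope_floor)
    k_at_cap = float(
        _k600_uncapped(v_cap, s, model, calibration, bias_correct, slope_floor)
    )
    out = np.empty_like(k_unc)
    capped = v > v_cap
    running = -np.inf
    for i in range(v.size):
        if capped[i]:
            out[i] = running if np.isfinite(running) else k_at_cap
        else:
            out[i] = k_unc[i]
            running = max(running, out[i])
    return out, capped


def _fit_log10_model(y_log10, X, n_min: int = 10):
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y_log10, X).fit()
    model = RegressionModel(
        intercept=float(res.params[0]),
        slopes=tuple(float(p) for p in res.params[1:]),
        mse=float(res.ssr / res.df_resid),
        adj_r2=float(res.rsquared_adj),
        n=int(res.nobs),
    )
    return model, res


def _check_fit_data(slopes_pct, n: int) -> None:
    if n < 10:
        raise ValueError(f"need >= 10 observations to fit, got {n}")
    cats = {slope_category(s) for s in np.asarray(slopes_pct, dtype=float)}
    if len(cats) < 2:
        raise ValueError("fit data must span more than one slope category")


def fit_velocity_model(
    data: pd.DataFrame,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
    full_output: bool = False,
):
    """Fit log10 V = a + b1 log10 D + b2 log10 S by OLS.

    `data` needs columns ``velocity_ms, q_Ls, slope_pct``.
    """
    _check_fit_data(data["slope_pct"], len(data))
    y = np.log10(data["velocity_ms"].to_numpy(dtype=float))
    X = np.column_stack(
        [
            np.log10(data["q_Ls"].to_numpy(dtype=float)),
            np.log10(_floor_slope(data["slope_pct"], slope_floor)),
        ]
    )
    model, res = _fit_log10_model(y, X)
    return (model, res) if full_output else model


def fit_k600_model(
    data: pd.DataFrame,
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
    full_output: bool = False,
):
    """Fit log10 k600 = a + b1 V + b2 log10 S by OLS.

    `data` needs columns ``k600_md, velocity_ms, slope_pct``; rows with
    non-positive or missing k600 (flagged negative-rate injections) are
    dropped before fitting.
    """
    data = data.loc[data["k600_md"].notna() & (data["k600_md"] > 0)]
    _check_fit_data(data["slope_pct"], len(data))
    y = np.log10(data["k600_md"].to_numpy(dtype=float))
    X = np.column_stack(
        [
            data["velocity_ms"].to_numpy(dtype=float),
            np.log10(_floor_slope(data["slope_pct"], slope_floor)),
        ]
    )
    model, res = _fit_log10_model(y, X)
    return (model, res) if full_output else model


def calibration_factor(measured, modelled, through_origin: bool = True) -> float:
    """Slope of the regression of measured on modelled values.

    Used to rescale modelled k600 so that the model does not
    overestimate in the high range; through-origin by default (a pure
    rescaling), with an intercept-including alternative behind the flag.
    """
    x = np.asarray(modelled, dtype=float)
    y = np.asarray(measured, dtype=float)
    if through_origin:
        return float(np.sum(x * y) / np.sum(x * x))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# ice mask


def ice_mask(air_temp: pd.Series) -> pd.Series:
    """Mark days inside runs of more than 3 consecutive sub-zero days.

    `air_temp` is a daily mean series (deg C) on a contiguous daily
    index; returns a boolean series, True where the day is excluded
    (streams assumed frozen).
    """
    below = air_temp < 0
    # label contiguous runs and measure their lengths
    run_id = (below != below.shift()).cumsum()
    run_len = below.groupby(run_id).transform("sum")
    return below & (run_len > 3)
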