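"""Sensor despiking, network interpolation and separable reconstruction."""

import numpy as np
import pandas as pd
import pytest

from streamghg import concentrations as cm
from streamghg import network as net


def brute_force_despike(series, threshold=0.2, window=pd.Timedelta("12h")):
    """Reference windowed scan, written independently of the implementation."""
    keep = []
    for i, (t, v) in enumerate(series.items()):
        before = series[(series.index >= t - window) & (series.index < t)]
        after = series[(series.index > t) & (series.index <= t + window)]
        checks = []
        for win in (before, after):
            if len(win):
                m = win.mean()
                checks.append(abs(v - m) > threshold * abs(m))
        if checks and all(checks):
            continue
        keep.append(t)
    return series.loc[keep]


def hourly_series(values, start="2014-06-01"):
    idx = pd.date_range(start, periods=len(values), freq="h")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestDespike:
    def test_constant_series_unchanged(self):
        s = hourly_series([100.0] * 50)
        assert cm.despike_sensor(s).equals(s)

    def test_single_spike_removed(self):
        vals = [100.0] * 50
        vals[25] = 150.0
        s = hourly_series(vals)
        out = cm.despike_sensor(s)
        assert len(out) == 49
        assert s.index[25] not in out.index

    def test_endpoint_uses_single_window(self):
        vals = [100.0] * 30
        vals[0] = 150.0
        s = hourly_series(vals)
        assert s.index[0] not in cm.despike_sensor(s).index

    def test_matches_brute_force_on_random_walk_with_spikes(self):
        rng = np.random.default_rng(8)
        base = 100 * np.exp(np.cumsum(rng.normal(0, 0.01, 400)))
        spikes = rng.random(400) < 0.05
        vals = np.where(spikes, base * rng.uniform(1.3, 2.0, 400), base)
        s = hourly_series(vals)
        out = cm.despike_sensor(s)
        expected = brute_force_despike(s)
        assert out.index.equals(expected.index)
        # never removes more than the brute-force 20% scan
        assert len(out) >= len(expected)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(9)
        vals = 100 + rng.normal(0, 1.0, 200)
        vals[::37] *= 1.6
        s = hourly_series(vals)
        once = cm.despike_sensor(s)
        twice = cm.despike_sensor(once)
        assert once.equals(twice)

    def test_empty_series(self):
        s = pd.Series(dtype=float, index=pd.DatetimeIndex([]))
        assert cm.despike_sensor(s).empty


def two_branch_network():
    def prof(branch, length, width=1.0):
        return pd.DataFrame(
            {
                "branch_id": branch,
                "distance_m": [0.0, length],
                "elevation_m": [60.0, 58.0],
                "drainage_km2": [0.5, 2.0] if branch != "hw2" else [0.2, 1.0],
                "width_m": width,
            }
        )

    profile = pd.concat(
        [prof("hw1", 1000.0), prof("hw2", 600.0), prof("main", 1000.0)]
    )
    return net.Network(
        profile=profile, topology={"hw1": "main", "hw2": "main", "main": None}
    )


def reach_row(reach_id, branch, midpoint):
    return {
        "reach_id": reach_id,
        "branch_id": branch,
        "midpoint_m": midpoint,
        "start_m": midpoint - 10,
        "end_m": midpoint + 10,
    }


class TestSpatialInterpolate:
    def test_equal_samples_give_uniform_field(self):
        network = two_branch_network()
        survey = pd.DataFrame(
            {
                "branch_id": ["hw1", "main"],
                "distance_m": [100.0, 800.0],
                "conc": [10.0, 10.0],
            }
        )
        reaches = pd.DataFrame(
            [reach_row("r1", "hw1", 500.0), reach_row("r2", "main", 400.0)]
        )
        out = cm.spatial_interpolate(survey, network, reaches)
        assert out.to_numpy() == pytest.approx([10.0, 10.0])

    def test_linear_midpoint(self):
        network = two_branch_network()
        survey = pd.DataFrame(
            {
                "branch_id": ["main", "main"],
                "distance_m": [0.0, 1000.0],
                "conc": [10.0, 20.0],
            }
        )
        reaches = pd.DataFrame([reach_row("mid", "main", 500.0)])
        out = cm.spatial_interpolate(survey, network, reaches)
        assert out.loc["mid"] == pytest.approx(15.0)

    def test_confluence_is_discharge_weighted_mean(self):
        network = two_branch_network()
        # samples only at the headwater mouths; main stem head inherits
        # the drainage-area weighted mean (areas 2.0 and 1.0 at mouths)
        survey = pd.DataFrame(
            {
                "branch_id": ["hw1", "hw2"],
                "distance_m": [1000.0, 600.0],
                "conc": [30.0, 12.0],
            }
        )
        reaches = pd.DataFrame([reach_row("head", "main", 0.0)])
        out = cm.spatial_interpolate(survey, network, reaches)
        assert out.loc["head"] == pytest.approx((30.0 * 2.0 + 12.0 * 1.0) / 3.0)

    def test_matches_brute_force_per_edge_interpolation(self):
        network = two_branch_network()
        rng = np.random.default_rng(10)
        survey_rows = []
        for branch, length in (("hw1", 1000.0), ("hw2", 600.0), ("main", 1000.0)):
            for d in np.sort(rng.uniform(0, length, 3)):
                survey_rows.append(
                    {
                        "branch_id": branch,
                        "distance_m": d,
                        "conc": float(rng.uniform(5, 50)),
                    }
                )
        survey = pd.DataFrame(survey_rows)
        reaches = pd.DataFrame(
            [reach_row(f"r{i}", "main", d) for i, d in enumerate((100, 400, 900))]
        )
        out = cm.spatial_interpolate(survey, network, reaches)
        # brute force: virtual head sample then per-edge linear interp
        main_s = survey[survey["branch_id"] == "main"].sort_values("distance_m")
        head_vals = []
        for b, wt in (("hw1", 2.0), ("hw2", 1.0)):
            bs = survey[survey["branch_id"] == b].sort_values("distance_m")
            head_vals.append(
                (np.interp(network.branch_length(b), bs["distance_m"], bs["conc"]), wt)
            )
        head = sum(v * w for v, w in head_vals) / sum(w for _, w in head_vals)
        xs = np.concatenate(([0.0], main_s["distance_m"].to_numpy()))
        cs = np.concatenate(([head], main_s["conc"].to_numpy()))
        for i, d in enumerate((100, 400, 900)):
            assert out.loc[f"r{i}"] == pytest.approx(float(np.interp(d, xs, cs)))

    def test_output_bounded_by_samples_on_unbranched_segment(self):
        network = two_branch_network()
        rng = np.random.default_rng(11)
        survey = pd.DataFrame(
            {
                "branch_id": "main",
                "distance_m": np.linspace(0, 1000, 6),
                "conc": rng.uniform(5, 60, 6),
            }
        )
        reaches = pd.DataFrame(
            [reach_row(f"r{i}", "main", d) for i, d in enumerate(range(50, 1000, 100))]
        )
        out = cm.spatial_interpolate(survey, network, reaches)
        assert out.min() >= survey["conc"].min() - 1e-12
        assert out.max() <= survey["conc"].max() + 1e-12

    def test_no_samples_rejected(self):
        network = two_branch_network()
        with pytest.raises(ValueError):
            cm.spatial_interpolate(
                pd.DataFrame(columns=["branch_id", "distance_m", "conc"]),
                network,
                pd.DataFrame([reach_row("r", "main", 10.0)]),
            )


class TestRatiosAndReconstruction:
    def setup_method(self):
        self.assignment = pd.Series({"r1": "a1", "r2": "a1"})

    def test_reach_on_anchor_has_unit_ratio_zero_cv(self):
        interpolated = pd.DataFrame(
            {"s1": [5.0, 10.0], "s2": [8.0, 16.0]}, index=["r1", "r2"]
        )
        anchors = pd.DataFrame({"s1": [5.0], "s2": [8.0]}, index=["a1"])
        out = cm.relative_ratios(interpolated, anchors, self.assignment)
        assert out.loc["r1", "ratio"] == pytest.approx(1.0)
        assert out.loc["r1", "cv"] == pytest.approx(0.0)
        assert out.loc["r2", "ratio"] == pytest.approx(2.0)
        assert out.loc["r2", "cv"] == pytest.approx(0.0)

    def test_known_multiplicative_field_recovered(self):
        rng = np.random.default_rng(12)
        field = pd.Series({"r1": 0.7, "r2": 2.4})
        cols = {}
        anchor_cols = {}
        for s in range(4):
            anchor = float(rng.uniform(5, 20))
            cols[f"s{s}"] = field * anchor
            anchor_cols[f"s{s}"] = anchor
        interpolated = pd.DataFrame(cols)
        anchors = pd.DataFrame(anchor_cols, index=["a1"])
        out = cm.relative_ratios(interpolated, anchors, self.assignment)
        assert out["ratio"].to_numpy() == pytest.approx(field.to_numpy())
        assert out["cv"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_gap_fill_linear_between_samples(self):
        cal = pd.date_range("2014-06-01", periods=15, freq="D")
        anchor_series = pd.DataFrame(
            {
                "anchor_id": ["a1", "a1"],
                "date": [cal[0], cal[14]],
                "conc": [10.0, 24.0],
            }
        )
        ratios = pd.DataFrame({"ratio": [1.0], "cv": [0.0]}, index=["r1"])
        conc, flags = cm.temporal_reconstruct(
            anchor_series, ratios, pd.Series({"r1": "a1"}), cal
        )
        assert conc.loc[cal[7], "r1"] == pytest.approx(17.0)
        assert not flags.to_numpy().any()

    def test_edges_carry_nearest_value_and_flag(self):
        cal = pd.date_range("2014-06-01", periods=10, freq="D")
        anchor_series = pd.DataFrame(
            {
                "anchor_id": ["a1", "a1"],
                "date": [cal[3], cal[6]],
                "conc": [10.0, 16.0],
            }
        )
        ratios = pd.DataFrame({"ratio": [2.0], "cv": [0.0]}, index=["r1"])
        conc, flags = cm.temporal_reconstruct(
            anchor_series, ratios, pd.Series({"r1": "a1"}), cal
        )
        assert conc.loc[cal[0], "r1"] == pytest.approx(20.0)
        assert conc.loc[cal[9], "r1"] == pytest.approx(32.0)
        assert flags.loc[cal[0], "r1"] and flags.loc[cal[9], "r1"]
        assert not flags.loc[cal[4], "r1"]

    def test_separable_field_reconstructed_exactly(self):
        # the method's own assumption: static spatial ratio x anchor series
        rng = np.random.default_rng(13)
        cal = pd.date_range("2014-05-01", periods=60, freq="D")
        g = pd.Series(np.exp(rng.normal(0, 0.3, 60)).cumsum() / 30, index=cal)
        ratios_true = {"r1": 0.5, "r2": 1.0, "r3": 3.2}
        anchor_series = pd.DataFrame(
            {"anchor_id": "a1", "date": cal, "conc": g.to_numpy()}
        )
        ratios = pd.DataFrame(
            {"ratio": list(ratios_true.values()), "cv": 0.0},
            index=list(ratios_true),
        )
        assignment = pd.Series({r: "a1" for r in ratios_true})
        conc, _ = cm.temporal_reconstruct(anchor_series, ratios, assignment, cal)
        for r, rho in ratios_true.items():
            assert conc[r].to_numpy() == pytest.approx(rho * g.to_numpy())


class TestUncertaintyPct:
    def test_max_rule(self):
        assert cm.uncertainty_pct([0.1, 0.6, 0.25]) == pytest.approx(60.0)
        assert cm.uncertainty_pct([0.0, 0.0]) == 0.0
        assert cm.uncertainty_pct([]) == 0.0
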