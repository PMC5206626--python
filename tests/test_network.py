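"""Network discretisation, discharge scaling and the regression models."""

import numpy as np
import pandas as pd
import pytest

from streamghg import network as net


def straight_profile(n=5, length=400.0, drop=2.0, width=1.0, branch="b1"):
    dist = np.linspace(0, length, n)
    return pd.DataFrame(
        {
            "branch_id": branch,
            "distance_m": dist,
            "elevation_m": 60.0 - drop * dist / length,
            "drainage_km2": 0.5 + dist / length,
            "width_m": width,
        }
    )


class TestDiscretize:
    def test_uniform_branch_splits_into_equal_reaches(self):
        network = net.Network(profile=straight_profile())
        reaches = net.discretize(network, dz=0.5)
        assert len(reaches) == 4
        assert reaches["length_m"].to_numpy() == pytest.approx([100.0] * 4)
        assert reaches["slope_pct"].to_numpy() == pytest.approx([0.5] * 4)
        assert (reaches["slope_category"] == "S1").all()

    def test_steep_segment_slope_and_category(self):
        prof = pd.DataFrame(
            {
                "branch_id": "b1",
                "distance_m": [0.0, 2.6],
                "elevation_m": [60.0, 59.5],
                "drainage_km2": [0.5, 0.5],
                "width_m": [0.7, 0.7],
            }
        )
        reaches = net.discretize(net.Network(profile=prof), dz=0.5)
        assert len(reaches) == 1
        assert reaches.loc[0, "slope_pct"] == pytest.approx(19.23, abs=0.01)
        assert reaches.loc[0, "slope_category"] == "S5"

    def test_conserves_length_and_relief_on_concave_profile(self):
        # concave profile: steepening downstream, random spacing
        rng = np.random.default_rng(0)
        dist = np.sort(rng.uniform(0, 1000, 40))
        dist = np.concatenate(([0.0], dist, [1000.0]))
        elev = 80.0 - 10.0 * (dist / 1000.0) ** 2
        prof = pd.DataFrame(
            {
                "branch_id": "b1",
                "distance_m": dist,
                "elevation_m": elev,
                "drainage_km2": 0.5 + dist / 1000.0,
                "width_m": 1.0,
            }
        )
        reaches = net.discretize(net.Network(profile=prof), dz=0.5)
        assert reaches["length_m"].sum() == pytest.approx(1000.0)
        assert reaches["drop_m"].sum() == pytest.approx(10.0)
        # steeper reaches are shorter: lengths strictly decrease downstream
        lengths = reaches["length_m"].to_numpy()
        assert all(a > b for a, b in zip(lengths[:-1], lengths[1:]))
        # coverage is exact and contiguous
        assert reaches["start_m"].iloc[0] == 0.0
        assert reaches["end_m"].iloc[-1] == pytest.approx(1000.0)
        assert reaches["start_m"].iloc[1:].to_numpy() == pytest.approx(
            reaches["end_m"].iloc[:-1].to_numpy()
        )

    def test_local_rises_flattened_with_warning(self, caplog):
        prof = straight_profile()
        prof.loc[2, "elevation_m"] += 1.5  # local bump
        with caplog.at_level("WARNING"):
            reaches = net.discretize(net.Network(profile=prof), dz=0.5)
        assert "flattened" in caplog.text
        assert (reaches["slope_pct"] >= 0).all()

    def test_width_power_law_fallback(self):
        prof = straight_profile()
        prof["width_m"] = np.nan
        reaches = net.discretize(
            net.Network(profile=prof), dz=0.5, width_power_law=(0.9, 0.35)
        )
        assert (
            reaches["width_m"].to_numpy()
            == pytest.approx(0.9 * reaches["drainage_km2"].to_numpy() ** 0.35)
        )


class TestSlopeCategory:
    @pytest.mark.parametrize(
        "slope,cat",
        [(0.0, "S1"), (0.5, "S1"), (1.0, "S2"), (1.99, "S2"), (2.0, "S3"),
         (4.0, "S4"), (6.0, "S5"), (19.3, "S5")],
    )
    def test_lower_inclusive_boundaries(self, slope, cat):
        assert net.slope_category(slope) == cat

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            net.slope_category(-0.1)


class TestDailyScaling:
    def test_exactly_proportional_data(self):
        s = net.fit_daily_scaling([1.0, 2.0, 4.0], [3.0, 6.0, 12.0])
        assert s.b == pytest.approx(3.0)
        assert s.r2 == pytest.approx(1.0)

    def test_single_station_rejected(self):
        with pytest.raises(ValueError):
            net.fit_daily_scaling([1.0], [3.0])
        with pytest.raises(ValueError):
            net.fit_daily_scaling([2.0, 2.0], [3.0, 4.0])

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(4)
        areas = np.array([0.4, 0.9, 2.5, 6.9])
        errs, r2s = [], []
        for _ in range(600):
            b_true = float(rng.uniform(1, 100))
            q = b_true * areas * np.exp(rng.normal(0, 0.05, 4))
            s = net.fit_daily_scaling(areas, q)
            errs.append(abs(s.b - b_true) / b_true)
            r2s.append(s.r2)
        errs = np.array(errs)
        assert errs.mean() < 0.05
        assert np.quantile(errs, 0.95) < 0.10
        assert min(r2s) > 0.9

    def test_reach_discharge_linear_in_area(self):
        s = net.DayScaling(date=None, b=10.0, r2=1.0, n_stations=4)
        assert net.reach_discharge(1.0, s) == pytest.approx(10.0)
        assert net.reach_discharge(3.0, s) == pytest.approx(3 * 10.0)


class TestPredictVelocity:
    def test_printed_equation_evaluation(self):
        v = net.predict_velocity(82.8, 7.5, bias_correct=False)
        assert v == pytest.approx(0.41668, abs=1e-4)

    def test_zero_mse_means_no_correction(self):
        model = net.RegressionModel(-1.323, (0.466, 0.056), mse=0.0)
        assert net.predict_velocity(82.8, 7.5, model=model) == pytest.approx(
            net.predict_velocity(82.8, 7.5, model=model, bias_correct=False)
        )
        assert model.smearing_factor() == 1.0

    def test_monotone_in_discharge_and_slope(self):
        assert net.predict_velocity(100.0, 5.0) > net.predict_velocity(50.0, 5.0)
        assert net.predict_velocity(50.0, 10.0) > net.predict_velocity(50.0, 5.0)

    def test_nonpositive_discharge_rejected(self):
        with pytest.raises(ValueError):
            net.predict_velocity(0.0, 5.0)


class TestPredictK600:
    def test_printed_equation_evaluation(self):
        k = net.predict_k600(0.3, 7.5, calibration=0.89, bias_correct=False)
        assert k == pytest.approx(62.98, abs=0.01)

    def test_intercept_only_closed_form(self):
        k = net.predict_k600(0.0, 1.0, calibration=1.0, bias_correct=False)
        assert k == pytest.approx(10**0.319, rel=1e-12)

    def test_above_cap_uses_reach_max(self):
        k = net.predict_k600(0.9, 5.0, reach_max=42.0)
        assert k == 42.0

    def test_above_cap_without_reach_max_warns_and_caps(self):
        with pytest.warns(UserWarning, match="cap"):
            k = net.predict_k600(0.9, 5.0)
        assert k == pytest.approx(net.predict_k600(0.7, 5.0))

    def test_series_running_max_semantics(self):
        v = np.array([0.3, 0.5, 0.9, 0.4, 1.2])
        k, capped = net.predict_k600_series(v, 5.0)
        assert list(capped) == [False, False, True, False, True]
        # first capped day sees the max of days 0-1; second sees days 0-3
        assert k[2] == pytest.approx(max(k[0], k[1]))
        assert k[4] == pytest.approx(max(k[0], k[1], k[3]))

    def test_strictly_increasing_below_cap(self):
        ks = [net.predict_k600(v, 3.0) for v in (0.1, 0.3, 0.5, 0.7)]
        assert all(a < b for a, b in zip(ks, ks[1:]))
        assert net.predict_k600(0.3, 8.0) > net.predict_k600(0.3, 2.0)


class TestModelFitting:
    @staticmethod
    def _simulate(model, n, sd, rng, kind):
        if kind == "velocity":
            d = np.exp(rng.uniform(np.log(4.5), np.log(275), n))
            s = np.exp(rng.uniform(np.log(0.3), np.log(20), n))
            x = np.column_stack([np.log10(d), np.log10(s)])
            y = model.intercept + x @ np.array(model.slopes) + rng.normal(0, sd, n)
            return pd.DataFrame(
                {"velocity_ms": 10.0**y, "q_Ls": d, "slope_pct": s}
            )
        v = rng.uniform(0.05, 0.7, n)
        s = np.exp(rng.uniform(np.log(0.3), np.log(20), n))
        x = np.column_stack([v, np.log10(s)])
        y = model.intercept + x @ np.array(model.slopes) + rng.normal(0, sd, n)
        return pd.DataFrame({"k600_md": 10.0**y, "velocity_ms": v, "slope_pct": s})

    def test_noiseless_fit_recovers_generating_coefficients(self):
        rng = np.random.default_rng(1)
        data = self._simulate(net.VELOCITY_MODEL, 21, 0.0, rng, "velocity")
        fit = net.fit_velocity_model(data)
        assert fit.intercept == pytest.approx(-1.323, abs=1e-6)
        assert fit.slopes[0] == pytest.approx(0.466, abs=1e-6)
        assert fit.slopes[1] == pytest.approx(0.056, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0)
        data = self._simulate(net.K600_MODEL, 53, 0.0, rng, "k600")
        fit = net.fit_k600_model(data)
        assert fit.intercept == pytest.approx(0.319, abs=1e-6)
        assert fit.slopes == pytest.approx((2.110, 1.026), abs=1e-6)

    def test_ci_coverage_at_published_noise_levels(self):
        # simulate at the published residual variances and sample sizes;
        # each coefficient's 95% CI should cover truth in >=90% of runs
        rng = np.random.default_rng(5)
        for model, n, var, kind in (
            (net.VELOCITY_MODEL, 21, 0.006, "velocity"),
            (net.K600_MODEL, 53, 0.050, "k600"),
        ):
            hits = []
            for _ in range(200):
                data = self._simulate(model, n, np.sqrt(var), rng, kind)
                fitter = (
                    net.fit_velocity_model if kind == "velocity" else net.fit_k600_model
                )
                _, res = fitter(data, full_output=True)
                ci = res.conf_int(0.05)
                truth = np.array([model.intercept, *model.slopes])
                hits.append((ci[:, 0] <= truth) & (truth <= ci[:, 1]))
            coverage = np.mean(hits, axis=0)
            assert (coverage >= 0.90).all(), (kind, coverage)

    def test_insufficient_data_rejected(self):
        rng = np.random.default_rng(2)
        small = self._simulate(net.VELOCITY_MODEL, 5, 0.0, rng, "velocity")
        with pytest.raises(ValueError, match="10 observations"):
            net.fit_velocity_model(small)
        one_cat = self._simulate(net.VELOCITY_MODEL, 12, 0.0, rng, "velocity")
        one_cat["slope_pct"] = 0.5
        with pytest.raises(ValueError, match="slope category"):
            net.fit_velocity_model(one_cat)


class TestCalibrationFactor:
    def test_identity_and_rescaling(self):
        x = np.array([1.0, 2.0, 5.0, 10.0])
        assert net.calibration_factor(x, x) == pytest.approx(1.0)
        assert net.calibration_factor(x, 2 * x) == pytest.approx(0.5)

    def test_matches_normal_equation_on_noisy_data(self):
        rng = np.random.default_rng(3)
        modelled = rng.uniform(1, 100, 50)
        measured = 0.89 * modelled + rng.normal(0, 2, 50)
        expected = np.sum(modelled * measured) / np.sum(modelled**2)
        assert net.calibration_factor(measured, modelled) == pytest.approx(expected)

    def test_unbiased_model_calibrates_to_one(self):
        rng = np.random.default_rng(6)
        modelled = rng.uniform(1, 100, 400)
        measured = modelled * np.exp(rng.normal(0, 0.05, 400) - 0.05**2 / 2)
        assert net.calibration_factor(measured, modelled) == pytest.approx(
            1.0, abs=0.02
        )


class TestIceMask:
    def test_all_positive_temperatures_empty_mask(self):
        temps = pd.Series(
            5.0, index=pd.date_range("2013-01-01", periods=30, freq="D")
        )
        assert not net.ice_mask(temps).any()

    def test_five_day_cold_run_excluded_three_day_kept(self):
        idx = pd.date_range("2013-01-01", periods=20, freq="D")
        temps = pd.Series(2.0, index=idx)
        temps.iloc[2:7] = -2.0  # 5 days -> excluded
        temps.iloc[10:13] = -1.0  # 3 days -> kept (not more than 3)
        mask = net.ice_mask(temps)
        assert mask.iloc[2:7].all()
        assert not mask.iloc[10:13].any()
        assert mask.sum() == 5

    def test_matches_brute_force_run_scan(self):
        rng = np.random.default_rng(7)
        idx = pd.date_range("2013-01-01", periods=400, freq="D")
        temps = pd.Series(rng.normal(1.0, 4.0, len(idx)), index=idx)
        mask = net.ice_mask(temps)
        # brute force: scan runs of consecutive sub-zero days
        expected = np.zeros(len(idx), dtype=bool)
        i = 0
        t = temps.to_numpy()
        while i < len(t):
            if t[i] < 0:
                j = i
                while j < len(t) and t[j] < 0:
                    j += 1
                if j - i > 3:
                    expected[i:j] = True
                i = j
            else:
                i += 1
        assert (mask.to_numpy() == expected).all()


class TestNetworkTopology:
    def test_path_distances_across_confluence(self):
        prof = pd.concat(
            [
                straight_profile(branch="hw1", length=200.0),
                straight_profile(branch="hw2", length=100.0),
                straight_profile(branch="main", length=300.0),
            ]
        )
        network = net.Network(
            profile=prof, topology={"hw1": "main", "hw2": "main", "main": None}
        )
        # same branch
        assert network.path_distance("main", 10.0, "main", 60.0) == 50.0
        # headwater point to main-stem point: down to mouth, then along main
        assert network.path_distance("hw1", 150.0, "main", 40.0) == 50.0 + 40.0
        # across the confluence between the two headwaters
        assert network.path_distance("hw1", 150.0, "hw2", 80.0) == 50.0 + 20.0

    def test_single_outlet_enforced(self):
        prof = straight_profile(branch="a")
        with pytest.raises(ValueError):
            net.Network(
                profile=pd.concat([prof, straight_profile(branch="b")]),
                topology={"a": None, "b": None},
            )
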