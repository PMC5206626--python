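#!/usr/bin/env python
"""Fit the velocity and k600 regression models to the tracer campaign.

Model 1 predicts log10 velocity from log10 discharge and log10 slope;
Model 2 predicts log10 k600 from velocity and log10 slope.  The
measured-vs-modelled calibration factor guards against overestimation
in the high range.  Coefficients are written as a pipeline config file.
"""

from pathlib import Path

import pandas as pd

from streamghg import network as net
from streamghg.config import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    obs = pd.read_csv(ROOT / "results" / "k600_observations.csv")
    vel_data = obs.drop_duplicates(["reach_id", "date"]).rename(
        columns={"q_mean_Ls": "q_Ls"}
    )
    vmodel = net.fit_velocity_model(vel_data)
    kmodel = net.fit_k600_model(obs)
    good = obs.loc[~obs["negative_rate"]]
    modelled = net._k600_uncapped(
        good["velocity_ms"].to_numpy(), good["slope_pct"].to_numpy(),
        kmodel, calibration=1.0, bias_correct=True, slope_floor=0.05,
    )
    cal = net.calibration_factor(good["k600_md"].to_numpy(), modelled)

    print("velocity model (log10 V ~ log10 D + log10 S):")
    print(f"  intercept {vmodel.intercept:+.3f}, slopes "
          f"({vmodel.slopes[0]:.3f}, {vmodel.slopes[1]:.3f}), "
          f"adjR2 {vmodel.adj_r2:.3f}, MSE {vmodel.mse:.4f}, n {vmodel.n}")
    print("k600 model (log10 k600 ~ V + log10 S):")
    print(f"  intercept {kmodel.intercept:+.3f}, slopes "
          f"({kmodel.slopes[0]:.3f}, {kmodel.slopes[1]:.3f}), "
          f"adjR2 {kmodel.adj_r2:.3f}, MSE {kmodel.mse:.4f}, n {kmodel.n}")
    print(f"calibration factor (measured ~ modelled, through origin): {cal:.3f}")

    cfg = PipelineConfig(velocity_model=vmodel, k600_model=kmodel, calibration=cal)
    out = ROOT / "results" / "fitted_models.yaml"
    cfg.to_yaml(out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
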