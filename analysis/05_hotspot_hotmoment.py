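#!/usr/bin/env python
"""Hot-spot/hot-moment analysis: who emits, where and when.

Builds the slope-category and discharge-ratio tables (category means
relative to the network mean) and quantifies how much a survey
restricted to flat reaches and moderate-flow days would underestimate
the true network totals.
"""

from pathlib import Path

import pandas as pd

from streamghg.io import read_inputs
from streamghg.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    inputs = read_inputs(ROOT / "scratch" / "data" / "default")
    result = run_pipeline(inputs)
    s = result.summary

    table = pd.concat(
        [
            s.slope_ratios.rename_axis("category"),
            s.discharge_ratios.rename_axis("category"),
        ]
    )
    out = ROOT / "results" / "category_ratios.csv"
    table.round(3).to_csv(out)
    print("slope categories (ratio of category mean to network mean):")
    print(s.slope_ratios.round(2).to_string())
    print("\ndischarge-ratio bins:")
    print(s.discharge_ratios.round(2).to_string())

    ok = result.states.loc[~result.states["excluded"]]
    total_area = result.reaches["area_m2"].sum()
    n_days = ok["date"].nunique()
    mean_q = ok.groupby("reach_id")["discharge_Ls"].transform("mean")
    sub = ok.loc[(ok["slope_category"] == "S1") & (ok["discharge_Ls"] <= mean_q)]
    print("\nnaive survey confined to <1% slopes and <=mean-discharge days:")
    for gas, mass_col, molar in (
        ("CH4", "mass_CH4_kg", 16.04 / 1e6),
        ("CO2", "mass_CO2_Mg", 44.01 / 1e9),
    ):
        true_total = ok[mass_col].sum()
        naive = sub[f"flux_{gas}"].mean() * total_area * n_days * molar
        print(f"  {gas}: {100 * naive / true_total:.0f}% of the full-network total")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
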