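#!/usr/bin/env python
"""Generate the synthetic catchments used by the downstream analyses.

Writes two input bundles: the default (noisy) scenario and its
zero-noise twin used for validation.  Bulky inputs go to scratch/;
later analysis steps read them from there.
"""

import sys
from pathlib import Path

from streamghg.io import write_inputs
from streamghg.synthetic import CatchmentScenario, generate_catchment

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    for label, zero_noise in (("default", False), ("zero_noise", True)):
        scenario = CatchmentScenario(seed=SEED, zero_noise=zero_noise)
        inputs = generate_catchment(scenario)
        out = ROOT / "scratch" / "data" / label
        write_inputs(inputs, out)
        reaches = inputs.truth["reaches"]
        print(f"[{label}] seed {SEED}: wrote input bundle to {out}")
        print(
            f"  network: {len(reaches)} reaches, "
            f"{reaches['length_m'].sum():.0f} m channel, "
            f"{reaches['area_m2'].sum():.0f} m2 stream surface"
        )
        shares = (
            100 * reaches.groupby("slope_category")["area_m2"].sum()
            / reaches["area_m2"].sum()
        )
        print("  areal slope-category shares (%):")
        print(shares.round(1).to_string())
        print(
            f"  injections: {len(inputs.injections)} observations on "
            f"{inputs.injections['reach_id'].nunique()} reaches"
        )


if __name__ == "__main__":
    main()
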