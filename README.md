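# streamghg

Upscaling CH₄ and CO₂ emissions from a headwater stream network.

Streams vent large amounts of methane and carbon dioxide, but the
evasion is wildly uneven: short, steep, turbulent reaches and brief
high-discharge events can dominate the annual budget of a whole
catchment ("hot spots" and "hot moments"). Estimating a network total
therefore requires resolving, for every reach and every day, the gas
transfer velocity, the dissolved gas concentration, and the stream
surface area — from measurements that are inevitably sparse in space
and time. `streamghg` implements that upscaling chain for a hemiboreal
forest catchment setting and ships a seeded synthetic-catchment
generator with known ground truth, so the entire chain is testable end
to end without field data.

## The method

**Gas transfer velocity from tracer injections.** A volatile, inert
tracer (propane) is injected at the top of a short reach; its
first-order loss over the reach travel time τ (min) gives the gas
exchange rate, corrected for dilution by lateral groundwater inflow
through the up/downstream discharge ratio:

    rate = (1/τ) · ln[ (C_U · Q_U) / (C_D · Q_D) ]        (min⁻¹)

Multiplying by mean depth converts the rate to a transfer velocity
*k* (m d⁻¹), normalised across gases and temperatures via Schmidt
numbers:

    k₆₀₀ = k · (600 / Sc)^(−1/2),   k_gas = k₆₀₀ · (Sc_gas / 600)^(−1/2)

with Sc = 600 the freshwater Schmidt number of CO₂ at 20 °C.

**Network k₆₀₀ model.** Daily discharge everywhere on the network comes
from the drainage-area scaling *D = bA*, refitted through the origin
across gauging stations each day. Two log₁₀-linear regressions then
predict water velocity from discharge and channel slope, and k₆₀₀ from
velocity and slope (defaults: log₁₀V = −1.323 + 0.466·log₁₀D +
0.056·log₁₀S; log₁₀k₆₀₀ = 0.319 + 2.110·V + 1.026·log₁₀S), with a
smearing correction on the back-transform, a measured-vs-modelled
calibration factor (default 0.89), and a 0.7 m s⁻¹ velocity cap above
which the reach-specific maximum modelled k₆₀₀ is used. The network is
discretised into reaches of fixed 0.5 m elevation drop, so steep
terrain yields short reaches.

**Concentrations.** Dissolved CH₄ and CO₂ are reconstructed assuming a
separable field: a static spatial pattern (per-reach ratio to the
nearest temporally resolved anchor station, from linear interpolation
of survey campaigns along the channel) times the anchor's time series
(biweekly bottle samples for CH₄; despiked, daily-averaged sensor
records for CO₂). The maximum per-reach coefficient of variation of
the interpolation ratios sets the emission uncertainty bounds.

**Fluxes.** Per reach and day, F = k_gas · (C_aq − C_eq) with C_eq from
Henry's law, integrated over reach surface areas into annual network
totals (CH₄ in kg yr⁻¹, CO₂ in Mg yr⁻¹), CO₂-equivalents (GWP 28), and
category tables by slope class (S1 0–1% … S5 6–21%) and discharge
ratio bin. Days inside runs of more than three consecutive sub-zero
days are excluded as frozen.

## Worked example

The analysis drivers run the whole chain on a synthetic catchment
(`python analysis/01_simulate_catchment.py` … `06_zero_noise_validation.py`),
or equivalently through the CLI:

```sh
streamghg simulate --seed 1 --out scratch/data/default
streamghg summarize --inputs scratch/data/default --out results/summary.json
```

On the default seed-1 catchment the tracer campaign spans 0.5–558.7
m d⁻¹ with steep reaches ~15× above flat ones; the fitted velocity and
k₆₀₀ models reach adjusted R² of 0.93/0.94; and the upscaling prints:

```
mean annual: CH4 1213.7 (204.3-2223.2) kg yr-1, CO2 103.79 (85.91-121.66) Mg yr-1
CO2-equivalents (GWP 28): 137.8 (91.6-183.9) Mg yr-1, CH4 share 25%
```

The hot-spot table shows the structural result: the flattest category
holds ~89% of the stream area but emits at ~0.2× the network-mean areal
rate, while the steepest ~1% of area emits at ~4× the mean; a naive
survey confined to flat reaches and at-or-below-mean discharge days
would recover only ~37% (CH₄) and ~34% (CO₂) of the true totals. On
the zero-noise twin the pipeline reproduces the generator-true annual
totals to ~1e-16 relative error and recovers the generating regression
coefficients exactly — the master end-to-end check.

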