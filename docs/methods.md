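# Methods

This note documents the models implemented in `streamghg`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Gas physics

Concentrations are carried internally in μM (numerically equal to
mmol m⁻³), transfer velocities in m d⁻¹ and fluxes in mmol m⁻² d⁻¹, so
F = k·(C_aq − C_eq) composes without unit factors; conversions happen
only at I/O boundaries.

**Schmidt numbers.** CH₄ and CO₂ use the Wanninkhof fourth-order
freshwater polynomials in temperature (°C). The fourth-order CO₂ fit
evaluates to 600.3 at 20 °C, preserving the defining identity of the
k₆₀₀ convention to the nearest integer (the older third-order fit gives
599.4, which breaks it); that identity is why the fourth-order set is
the default here. Propane has no standard freshwater polynomial, so
Sc = ν(T)/D(T) with ν from a Vogel viscosity and Kell density
correlation for pure water, and D an Arrhenius fit anchored at
D(20 °C) ≈ 1.10×10⁻⁵ cm² s⁻¹ with activation temperature 2137 K,
consistent with the Wise & Houghton propane diffusivity data. The fit
parameters sit on the `GasSpec` and can be swapped. All Schmidt fits
are accepted on 0–35 °C; outside that range a `ValueError` names the
gas and bounds.

**Solubility.** CO₂ uses the Weiss-type freshwater function; CH₄ the
Yamamoto-type freshwater Bunsen solubility divided by 22.414 L mol⁻¹;
propane a van 't Hoff extrapolation (only used for completeness — the
tracer analysis works in relative concentrations with C_eq = 0). The
equilibrium temperature is always the record's water temperature; there
is no hidden global.

**CO₂-equivalents** use a mass-based 100-yr GWP of 28 for CH₄
(overridable); CH₄ is carried in kg and CO₂ in Mg throughout (molar
masses 16.04 and 44.01 g mol⁻¹).

## Tracer injections

The dilution-corrected rate is (1/τ)·ln[(C_U·Q_U)/(C_D·Q_D)]: scaling
the downstream concentration by Q_D/Q_U undoes the lateral groundwater
dilution, so only degassing contributes. When Q_U = Q_D it reduces
exactly to the plain two-point rate, and the result is invariant to the
arbitrary scale of the relative tracer concentrations. Negative rates
(apparent downstream tracer gain) are physically impossible, so they
are returned with a warning, flagged in the observation table, and
excluded from model fitting.

The independent cross-check `flux_based_k` treats the tracer lost from
a water column of the reach's mean depth over the travel time as a
flux and divides by the arithmetic mean of the end concentrations.
This is a genuinely different discretisation of the same physics: for a
tracer loss fraction L the two differ by a factor
[−ln(1−L)] / [2L/(2−L)], under 2% for L ≤ 0.40. The synthetic
injection study therefore caps the designed per-run loss at 35% — the
field-design analogue of moving the downstream sampling station up a
steep cascade so the downstream concentration stays well quantified —
which keeps the dual-route agreement inside 2% without making the two
routes algebraically identical.

One k₆₀₀ value is computed per observation row (downstream sampling
replicate), with the per-campaign mean reach depth.

## Network model

**Discretisation.** Reaches accumulate a fixed dz = 0.5 m of elevation
drop (final partial reach kept), so reach length adapts to terrain and
slope = 100·drop/length. Local elevation rises in the profile are
flattened to zero drop with a logged warning. Reach width is the mean
of the piecewise-linear profile width over the reach span (surface area
= length × width); when the profile carries no widths a user-supplied
width–drainage power law w = c·Aᵉ is applied at the reach midpoint.
Slope categories are half-open and lower-inclusive — S1 [0,1), S2
[1,2), S3 [2,4), S4 [4,6), S5 [6,∞) percent — so assignment is
deterministic at the printed boundaries.

**Discharge.** D = bA is fitted through the origin (the scaling has no
intercept) per day across stations; r² is reported as the fraction of
variance about the mean explained, clipped to [0,1].

**Regression models.** Ordinary least squares (statsmodels) on the
stated transformed scales. Back-transform from log₁₀ predictions uses
the multiplicative smearing factor exp(mse·ln(10)²/2), the lognormal
bias correction with mse the residual mean square on the log₁₀ scale.
Model-1 velocities are bias-corrected before entering Model 2, and the
calibration factor (slope of measured on modelled k₆₀₀, through the
origin — a pure rescaling; an intercept variant sits behind a flag) is
applied after the smearing correction. Slopes are floored at 0.05%
before log₁₀ (the flattest category starts at 0 and log 0 is
undefined); the floor is a config constant.

**Velocity cap.** The k₆₀₀ model is trusted only up to 0.7 m s⁻¹.
Above the cap a reach receives its running maximum of previously
modelled (v ≤ cap) k₆₀₀ values — "previously" meaning up to that date,
which keeps the rule causal and order-deterministic; if the cap is hit
before any in-range day the model is evaluated at the cap itself, with
a warning.

**Ice mask.** Days inside any run of more than 3 consecutive sub-zero
daily-mean air temperatures are excluded (streams assumed frozen);
excluded days stay in the reach-day table with a flag rather than being
dropped.

## Concentration field

Sensor despiking removes a value deviating by more than 20% from the
mean of the 12 h window before it and the 12 h window after it (the
point itself excluded from its windows; endpoints judged by the single
available window).

Spatial interpolation is linear in along-channel distance between
survey samples within a branch, with constant extrapolation beyond the
terminal samples. At a confluence the downstream branch starts from
the drainage-area-weighted mean of the merging branches' endpoint
values — drainage area is the discharge weight, since D = bA makes the
two proportional with b cancelling. Branches without samples inherit
the value at their junction. Each reach maps to the nearest anchor
station by along-channel network distance; field protocols rarely pin
this assignment down, so nearest-along-network is the documented
default here.

Per survey, the ratio of each reach's interpolated concentration to its
anchor's gap-filled concentration on the survey date is computed; the
per-reach ratio is the mean over surveys and its CV (sd/mean, sample
sd) feeds the uncertainty bound, 100 × the maximum CV over reaches.
Reconstruction multiplies the anchor's daily series (linear
interpolation between sampled days; nearest value, flagged, outside the
sampled span) by the reach ratio. The reconstruction is exact when the
field is separable — spatial ratio × anchor series — which is the
method's own assumption; reach-days with no anchor value at all are
excluded from totals, with the exclusion fraction reported.

## Emission aggregation

Reach-day masses are F × area × molar mass; annual totals sum
non-excluded reach-days per calendar year, and the headline totals are
the mean annual values over the years present. Category tables report
each category's mean areal flux (and mean k₆₀₀) relative to the
network-wide mean, plus percent stream area (slope categories) or
percent reach-day occurrence (discharge-ratio bins: ≤1, then
lower-inclusive 1–2, 2–3, 3–4, >4 relative to each reach's mean
discharge). A per-reach up/downstream mass balance,
F = Q·86.4·ΔC/area, serves as an independent check on k-based fluxes
over steep, strongly degassing sections; with moderate drawdown the two
agree within ~10%, and the comparison degrades as the along-reach
concentration drop becomes large (the arithmetic gradient then
overstates the log-mean one).

## Synthetic catchment generator

The generator emulates the study design so each stage can be validated
against known truth:

* **Network**: three branches (two headwaters joining a main stem),
  84 fixed-drop reaches whose slope-category counts are shaped so the
  areal shares land near 90/5/3/1/1% for S1…S5 (~5–6 km of channel,
  ~6000 m² of stream surface); widths follow w = 0.9·A^0.35. The
  profile is emitted at the reach boundaries, so `discretize` recovers
  the generated reaches exactly.
* **Discharge**: D = b(t)·A with seasonal baseflow, lognormal AR(1)
  dynamics, storm multipliers (3–8×, ~5% of days, populating all five
  discharge-ratio bins), a 1.7× wetter second year, and 5% lognormal
  station noise.
* **Concentrations**: a separable field s(reach)·g(t) with a smooth
  downstream trend, per-gas spatial scatter (CH₄ log₁₀-sd 0.45 ≫ CO₂
  0.12, mirroring the much larger spatial variability of CH₄), CH₄
  temporal signal piecewise linear between biweekly knots (so anchor
  gap-filling can be exact), hourly CO₂ sensor series with a diel cycle
  and ~1% condensation spikes, 20 survey points (4 of them anchors),
  5 CH₄ / 7 CO₂ survey dates, and per-sample survey noise representing
  measurement error plus non-separability.
* **Injections**: per-observation true k₆₀₀ drawn from the published
  regression surface with log₁₀ noise at the published residual
  variances (0.006 for velocity, 0.050 for k₆₀₀), truncated to the
  measured envelope 0.2–558.7 m d⁻¹, forward-modelled as
  c_down = c_up·exp(−rate·τ)·(q_up/q_down) with a 0.5% groundwater
  gain and the 35% loss-fraction design cap.

With `zero_noise=True` every stochastic term is off and the pipeline
must reproduce generator truth to float tolerance; this is asserted in
the test suite (annual totals to ~1e-9 relative, regression
coefficients to 1e-9 absolute).

**What the generator does not emulate.** Concentrations are not
coupled to degassing: real steep reaches show drawn-down concentrations
because high k depletes the dissolved pool, while the generated spatial
pattern is independent of slope. Consequently the synthetic network's
mean areal fluxes run higher, and the steep categories' emission ratios
are driven almost entirely by k. Passing tests therefore demonstrate
that the upscaling machinery is correct under the method's own
assumptions — not that those assumptions hold in any particular field
catchment. There is likewise no rainfall–runoff model, no hydrodynamic
routing, no ebullition, and no carbonate-system speciation (CO₂ is
treated as the dominant DIC form).

## Problem sizes and numerical choices

The default scenario spans 730 days × 84 reaches (~61k reach-days,
~3 s per full pipeline run) with a ~21-occasion, ~53-observation
tracer campaign matching the published sample sizes; the
parameter-recovery suite runs 200 replicates per model. Determinism:
a single scenario seed feeds per-stage child generators, so every
artifact is reproducible byte-for-byte; regression fitting, the
running-max cap and the run-length ice scan are deterministic. Ties and
degenerate inputs: ratio = 1 falls in the first discharge bin (≤ 1);
slope exactly on a category boundary goes to the upper category
(lower-inclusive); a zero-variance daily scaling reports r² = 1; a
single-survey ratio has CV 0; an empty sensor series despikes to empty.

## Limitations

* The exact typeset form of the dilution-corrected rate equation and of
  the emission equation were reconstructed from their stated physics
  (first-order loss with a discharge-ratio correction; the general
  diffusive flux law); both reduce to standard forms and are kept
  switchable/isolated should an alternative reading be preferred.
* The calibration factor and smearing correction are applied in a fixed
  order (smearing first, then calibration); the reverse order differs
  only by a constant rescaling of the calibration factor.
* Uncertainty bounds are symmetric relative bounds from the maximum
  interpolation-ratio CV; they do not propagate discharge, k-model or
  temperature uncertainty.
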