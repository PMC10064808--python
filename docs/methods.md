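# Methods

## Physical model

Heat transport in the burned soil column is modelled as vertical conduction
only:

  C ∂T/∂t = k ∂²T/∂z²,  z ∈ [0, L], t ∈ [0, t_end]

with z = 0 at the soil surface, positive downward. The surface temperature
is prescribed (Dirichlet) by the fire forcing curve; the bottom of the
column (L = 15 cm by default) is held at the initial temperature,
emulating a sand tray acting as a heat sink beneath the experimental core.
A zero-flux (insulated) bottom is available (`bottom="zero_flux"`) for
columns without a sink. The initial condition is uniform T_init = 20 °C.

Assumptions: homogeneous soil (k and C constant in depth and temperature),
no lateral losses, no moisture transport. An optional evaporative energy
sink can be enabled (`latent_heat_theta`): each node carries
θ·ρ_w·L_v J m⁻² of latent capacity (θ volumetric water content, L_v =
2.26 MJ kg⁻¹) and its temperature is capped at 100 °C until the store is
consumed. It is off by default; all headline results use pure conduction.

### Forcing curve

The burn has three phases with durations t_ramp = 600 s, t_hold = 60 s,
t_decay = 1800 s:

- linear ramp from T_basal (20 °C) to T_max (450 or 600 °C);
- constant hold at T_max;
- exponential decay T(t) = T_basal + (T_max − T_basal)·e^(−k_d·t′),
  k_d = ln(100)/t_decay, so exactly 1% of the rise remains at the end of
  the decay phase.

The decay being three times longer than the ramp produces the right-skewed
pulse characteristic of fire. Phase boundaries are always sample points, so
the curve attains T_max exactly at t_ramp and holds it through
t_ramp + t_hold. Simulations longer than the curve clamp the forcing to its
final value. The 60 s hold is the default; experiments with longer burns at
maximum temperature are expressed through the `fire.hold_s` config key.

### Soil parameterization

Volumetric heat capacity comes from de Vries-style linear mixing of the
constituents (MJ m⁻³ K⁻¹): C = 1.92·x_mineral + 2.51·x_organic + 4.18·θ.
The default composition — x_mineral = 0.45, x_organic = 0.05, θ = 0.10,
bulk density 1.40 g cm⁻³ — is a generic dryland loam chosen once so that
all results are reproducible from the package alone; every value is
config-overridable. With the default conductivity k = 0.03 W cm⁻¹ K⁻¹
(= 3 W m⁻¹ K⁻¹, at the upper end of moist mineral soils) the diffusivity is
α = k/C ≈ 2.13 × 10⁻⁶ m² s⁻¹. Conductivity is held fixed rather than
computed from moisture, matching the single-γ parameterization of the
experiment this package models.

### Numerics

Space is discretized at dz = 0.1 cm over 15 cm; output is reported every
dt_out = 1 s. Time stepping is Crank–Nicolson (θ = 0.5) with a tridiagonal
solve per step (`scipy.linalg.solve_banded`). At this resolution the
stability number r = α·dt/dz² ≈ 2.1: an explicit scheme would be unstable
outright, and although Crank–Nicolson is unconditionally stable, it loses
the discrete maximum principle for r > 1 (spurious oscillation near sharp
forcing transients). The solver therefore substeps internally by default —
n_sub = ⌈r⌉ substeps per output step, giving r ≤ 1 per substep — which
preserves monotonicity at unchanged output cadence for ~3× cost (a full
default run takes well under a second). A fixed `substeps` argument
overrides this for accuracy studies.

Verification, all enforced by the test suite:

- agreement with the independent semi-infinite-solid closed form
  T_init + ΔT·erfc(z/(2√(αt))) to ≲0.01% of the rise (tolerance 2%) for a
  step forcing on a 30 cm column, depths 0.5–10 cm, t = 60–600 s;
- discrete maximum principle (no value outside the envelope of boundary and
  initial data), even under an instantaneous surface step;
- exact (≈1e-13 relative) discrete energy balance between interior enthalpy
  change and the Crank–Nicolson-consistent boundary flux integral;
- grid convergence: halving dz and dt_out moves the 3 cm peak by ~4 × 10⁻⁵
  of the rise (tolerance 1%).

## Exposure metrics and the mortality zone

Per-depth summaries are computed at the grid nodes at whole centimetres
1–10 cm (per-grid-node output via `include_nodes=True`): peak temperature
and its time over the full record, mean over the analysis window (1800 s =
the first 30 min, truncated with a warning if the record is shorter), and
time/degree-seconds above each threshold (50, 60, 100 °C defaults), counted
as samples × dt.

The mortality zone is the interval [0, D] with D the deepest
whole-centimetre depth whose **peak** temperature meets the lethal
threshold, 100 °C by default — a peak criterion rather than a
duration-weighted one, consistent with using wet-heat tolerance limits of
soil microbes as a bright line; degree-second metrics are reported but do
not enter the classification. Sub-threshold depths above D (impossible for
monotone pulse forcings, possible for exotic ones) are logged as gaps and
do not shrink the zone. Under the default parameterization the zone reaches
9 cm (600 °C burn) and 7 cm (450 °C burn); the claim that the top 3 cm are
within possible heat mortality is the conservative core of this interval.

## Observation statistics

**Thermocouple comparisons.** For each (fire temperature, depth) stratum,
all samples in the first 30 min are pooled across replicates per cover
(bare vs biocrust) and compared with a Welch unequal-variance t-test
(Welch–Satterthwaite degrees of freedom, two-sided p). Per-second samples
are deliberately treated as independent — reproducing the conventional
analysis of such experiments, not endorsing it — and every output carries
an autocorrelation caveat. No multiple-testing correction is applied.
Strata missing a cover or with fewer than two valid samples per group are
skipped with a warning. The published comparison table ships as a reference
fixture (`load_table1_reference`) for annotation only: the raw traces
behind it are not public, so those numbers are displayed, never recomputed.

**Model-vs-observation offset.** A trace is compared with the model at its
nominal depth (RMSE) and at every grid-step depth offset within ±2 cm; the
offset minimizing RMSE is reported, ties breaking toward the smaller
|offset|. This quantifies the "probe is about a centimetre off" diagnosis
that haphazard probe placement produces.

**CFU statistics.** Growth fractions are reported overall, per treatment
and per depth (percentages to one decimal). Pearson chi-squared tests
(no continuity correction) of presence/absence are run against fire
temperature (3 × 2: control/450/600) and against cover (2 × 2), pooling
over the other factors — both layouts are always emitted. The minimum
growth depth per treatment is the shallowest centimetre with ≥1 positive
replicate.

## Synthetic data generator

The generator emulates the study's observation processes at the study's
design sizes; its defaults are the study conditions, not tuning knobs.

**Thermocouple traces**: the simulated field sampled at each probe's
realized depth = nominal depth (2, 5, 8 cm) + one N(0, 0.5² cm) jitter draw
per probe (probes shift when cores are handled), plus N(0, 2² °C) noise per
sample; 6 replicates per treatment. A flat −10 °C offset is applied to
biocrust treatments — a systematic cover effect of realistic magnitude
(observed per-stratum mean differences span roughly 7–97 °C) so that the
six-stratum Welch table shows the bare-hotter pattern. Random streams are
split per probe (SeedSequence spawning), so adding replicates never
perturbs earlier draws.

**CFU grids**: each plate is an independent Bernoulli draw with
P(growth) = p_base · σ((T50 − peak(depth))/s), where peak(depth) comes from
the exposure summary of that treatment's fire level and controls use
peak = T_init (hence baseline culturability p_base). Defaults T50 = 100 °C,
s = 10 °C, p_base = 0.9: survival tracks the peak-temperature criterion of
the mortality zone, with a soft shoulder rather than a hard threshold.
Streams are split per (cover, fire, depth) stratum. Survival depends on
peak temperature only; duration effects are out of scope of the default
model.

**T50 recovery** maximizes the Bernoulli log-likelihood over a 1-D grid
(20–400 °C, 1 °C steps) with s and p_base fixed; ties break toward the
lower value, and estimates on the search boundary (all-positive or
all-negative grids) are returned flagged. At the default design the median
estimate over 50 seeds recovers the true midpoint within ±10 °C (observed:
exactly, with ~3 °C spread), and the error shrinks monotonically as
replicates grow (6 → 24 → 96).

What passing these tests shows — and does not. The generator reproduces the
*statistical structure* the experiment assumes (design size, noise scales,
depth-dependent survival driven by simulated peaks); it does not reproduce
real soil heterogeneity, probe dropout from overheating, temperature-
dependent conductivity, or community-level recovery dynamics, so green
tests validate the pipeline's correctness, not field realism.

## Pipeline and reproducibility

A single YAML config (unknown keys rejected) drives `run-all`: per fire
level it writes forcing, field, exposure and mortality-zone artifacts, then
synthetic traces with the Welch comparison table, the synthetic CFU grid
with chi-squared tests and the T50 fit, plots, and a text summary. All
stage seeds derive from the global seed via SeedSequence spawn keys (kept
below 2³¹); two runs with identical config and seed produce byte-identical
CSV/JSON outputs. The full default run (two fire levels at 0.1 cm / 1 s,
360 plates) completes in a few seconds on one CPU; the test suite runs the
same computations at the default resolution plus a half-resolution
convergence companion and a 50-seed recovery study, in well under a minute.

## Known limitations

- 1-D conduction ignores mug-wall and lateral effects and surface
  radiative/convective losses; the prescribed-temperature boundary absorbs
  them only insofar as the forcing curve reflects measured surface values.
- Constant conductivity and the off-by-default latent-heat sink mean
  near-boiling plateaus observed in wet soils are not reproduced in the
  default configuration.
- The Welch comparison inherits the independence idealization discussed
  above; its p-values are anticonservative for autocorrelated traces.
- The logistic lethal-peak survival model is a deliberate formalization of
  threshold reasoning; no quantitative survival-vs-temperature curve exists
  to calibrate it against, so T50/s/p_base are package defaults used for
  synthetic validation only.
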