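# Methods

## Scope and model structure

`rascycle` models a reconstituted Ras signaling system: Ras immobilised on
a bead, a GEF step input, GAP-mediated deactivation, and fluorescent
Ras-binding-domain (RBD) effectors whose surface accumulation is the
output. Everything is well-mixed mass action; time is in seconds and
concentrations in nM (bimolecular rate constants in nM⁻¹ s⁻¹). Membrane
biophysics — diffusion, nanoclustering, bilayer composition — is out of
scope, as are stochastic (Gillespie) dynamics and thermodynamic
cycle-closure constraints.

Three cycle topologies are provided.

1. **Two-state**: G (empty) + T → GT, GT → GD at `1e-4 × gap_level`
   (GAP activity folded into the hydrolysis rate constant, so
   `gap_level = 1` is the intrinsic rate), GD → G + D at `k_exch`,
   effector binding GT + EFF ⇌ GT_EFF (1e-4 on / 1e-3 off), and
   hydrolysis from the bound state GT_EFF → GD + EFF at 1e-4 s⁻¹.
   Exchange defaults to 0.05 s⁻¹ in this model.
2. **Competition**: the two-state cycle plus an explicit GAP species,
   GT + GAP ⇌ GT_GAP (1e-4 on; off/cat presets below) and committed
   hydrolysis GT_GAP → GD + GAP. Exchange defaults to 0.005 s⁻¹.
3. **Three-state**: the competition network plus a post-hydrolysis state
   GI that only relaxes to GD slowly (`k_gi_reset` = 1e-4 s⁻¹) and is not
   a substrate for exchange — i.e. refractory to GEF.

GEF is not a species in the constitutive models; its activity enters as
`k_exch = k_per_gef × [GEF]` with `k_per_gef` = 5e-6 nM⁻¹ s⁻¹, so 1 μM GEF
gives the canonical 0.005 s⁻¹. GAP kinetic presets: physiologic
(k_off 0.01, k_cat 1 s⁻¹), NF1-like (0.01, 0.1), p120-like (0.25, 0.4) and
a deliberately non-physiologic set (1e-4, 1e-4) under which even the
two-state-plus-competition model overshoots.

### GI routing

Which hydrolysis channels produce GI is configurable (`GIRouting`). The
default routes **only GAP-catalysed** hydrolysis to GI; intrinsic and
effector-bound hydrolysis go straight to GD. Routing every channel to GI
makes even GAP-free networks overshoot strongly (the slow intrinsic flux
still parks the pool in GI), which is not how GAP-free systems behave;
with GAP-only routing the model is monotone at zero GAP and transient at
high GAP, the observed phenotype. The per-channel flags let users explore
the alternative.

### Mutants and extra effectors

`MutantSpec` scales (i) GAP catalysis, (ii) intrinsic + effector-bound
hydrolysis, and (iii) effector off-rate. G12V defaults to (0, 1, 1): the
GAP still binds — and therefore still sequesters — but cannot catalyse.
`add_effector` adds an independent EFF_i/GT_EFF_i pair competing for the
same GT pool (one partner per GTPase at a time).

## Numerical integration

The nucleotide-binding mode (1 nM⁻¹ s⁻¹ against a 100,000 nM GTP pool,
i.e. ~1e5 s⁻¹) makes the ODE system genuinely stiff; it is integrated
with LSODA at rtol 1e-8 / atol 1e-12 (analytic Jacobian for pure
mass-action networks) on the 15-min sample grid over 42000 s. Simulations
validate non-negativity (tolerance −1e-9 nM) and conservation of the
GTPase, effector, GAP and GEF totals (relative 1e-6) on every run.
`steady_state` integrates in 42000 s chunks until every non-nucleotide
species satisfies |dx/dt| < 1e-9 nM/s (free T and D drift forever at the
cycle flux under the infinite-nucleotide idealisation, so they are
excluded); chunks that stall near equilibrium are retried with BDF and,
if needed, a relaxed atol.

The test suite cross-checks the adaptive solver against an independent
fixed-step explicit-Euler oracle (numba) to relative 1e-3. Oracle
scenarios use a 200 nM nucleotide pool so the fast binding mode lies
inside Euler's stability region at dt = 2e-4 s; with the full 1e5 nM pool
no tractable explicit step is stable.

## Output features

Features of a sampled output trace (`Timecourse`):

* `integrated_signal` — trapezoid integral over the full span. No
  quadrature rule is canonical here; trapezoid on the imaging grid is the
  simplest choice. Note the 15-min grid under-resolves the earliest output
  pulse of strongly driven high-GAP networks by a few percent relative to
  fine-grid quadrature.
* `initial_rate` — least-squares slope over the rise up to 10% of peak
  (minimum 3 points). The 10% window is a package choice, exposed as a
  module constant.
* `transient_score` — (peak − final)/peak clipped to [0, 1], with final
  the mean of the last 3 samples (robust to per-timepoint noise) and an
  explicit monotone-non-decreasing guard returning 0, so still-rising
  traces are never scored as transient. Any monotone-in-overshoot
  definition reproduces orderings, not absolute values.
* `pulse_width_s` — time spent above (peak + final)/2, with linear
  interpolation at the crossings.
* `distortion_score` and `feedback_gain` — ratios of integrated signals
  (mutant/WT and feedback/constitutive respectively) on a shared grid.
  Both are invariant to a common gain, so they can be computed on raw AU
  traces as well as on nM.

## Phase diagrams

`run_config_grid` runs the factorial GEF × GAP × Ras-density scan
(defaults 20/200/1000/2000 nM GEF — spanning the experimental 20 nM–2 μM
input range — 0/100/1000/10000 nM GAP, and the six canonical density
bins: 96 configurations; exact GEF/GAP level values beyond the printed
range are package choices and fully configurable). Ras surface density
maps to the model's Ras concentration linearly with 2500 molecules·μm⁻²
↔ 10 nM, tying the canonical bead density to the canonical model
concentration. Feature surfaces are interpolated bilinearly in
(log₁₀ GEF, log₁₀(GAP + ε)) with ε = 0.1 × the smallest nonzero GAP
level; isoclines are marching-squares contours whose points evaluate back
to the contour level under the interpolant. Integrated signal is
monotone non-increasing in GAP at every density; in GEF it is
non-decreasing to within ~1% (between 1 and 2 μM GEF the integral can dip
a few tenths of a percent because faster drive front-loads
refractory-state accumulation).

## Feedback architectures

Neither feedback mechanism comes with published rate equations; both rate
laws are this package's minimal encodings of the verbal designs, and all
constants are exposed.

* **Recruitment** (RBD-fused GEF): the GEF is a species binding GT
  (competing with effector and GAP); the exchange flux becomes
  `k_per_gef × ([GEF_free] + α·[GT_GEF]) × [GD]`. Defaults: a weak,
  fast-exchanging RBD arm (k_on 1e-4 nM⁻¹ s⁻¹, k_off 0.33 s⁻¹,
  K_d ≈ 3.3 μM) and a large surface-enhancement factor α = 1e6. The weak
  arm is deliberate: a C-Raf-affinity arm at 2 μM GEF would sequester the
  whole Ras•GTP pool away from the 50 nM effector, which is not what the
  measured high-GEF outputs look like; with the weak arm the fusion
  samples the pool without competing the effector off, and α carries the
  feedback strength (a single bead-bound GEF sees its 2-D-confined
  substrate at an enormously increased effective concentration). These
  are tuned design constants, not measured values. The well-mixed α
  factor deliberately ignores the spatial locality of bead-bound GEF.
* **Allosteric** (SOS-like): exchange becomes state-dependent,
  `k_exch = k_basal + (k_max − k_basal) · GT_tot/(K_A + GT_tot)` with
  GT_tot the sum of all GT-containing species; defaults
  k_basal = 0.1·k_max, K_A = 5 nM. A step input of protein is thereby a
  ramp input of activity, which dampens the overshoot of high-GAP
  networks. The allosteric output is bounded by the constitutive system
  run at k_max pointwise in monotone (GAP-free) regimes and in peak value
  generally; in strongly overshooting regimes its delayed peak can cross
  the constitutive trace after that has decayed, so a pointwise bound
  does not hold there.

## Ras density estimation

`Concentration (μM) = 4.287 × Intensity (AU)` from a solution
calibration; `density = concentration × 602 molecules·μm⁻³ μM⁻¹ ×
0.055 μm = 33.1 molecules·μm⁻² per μM`. The 55 nm figure is used directly
as the confinement length as printed, although the source text calls it a
"radius of confinement"; the arithmetic follows the printed formula. This
chain is a crude estimate by construction — relative densities between
beads are the meaningful quantity. Bin assignment to the six canonical
densities uses nearest-in-log₂ distance (the bins are ~2× spaced; linear
nearness would make the 10000 bin's lower shoulder unreachable), with
exact ties breaking to the lower bin.

## Synthetic bead data

The generator emulates the statistical structure of the bead microscopy
data with the simulator as ground truth:

* Densities lognormal around each bin centre (log-sd = `cv_bead`,
  default 0.25 — an assumption; the true within-bin distribution is
  unknown); radii uniform over 12–68 px so areas satisfy the macro's
  400–15000 px² particle filter; Ras-channel intensity is the density
  calibration inverted.
* Per bead, the configured network is simulated with total Ras =
  density × 0.004 nM and the bound-effector trajectory rendered to AU:
  `gain × trace × (perimeter/P_ref) × bead_factor + background +
  N(0, σ_add)`, with `bead_factor` lognormal(0, cv_bead). The default
  scenario is the three-state network, 1 μM GEF, no GAP, 50 nM effector,
  15-min frames over 42000 s. Signal scales with perimeter because the
  fluorescence lives on the bead surface — which is exactly why the
  downstream pipeline normalises to perimeter.
* Defaults gain 20 AU/nM, background 50 AU, σ_add 2 AU, cv_bead 0.25 are
  calibrated so that a 15-bead bin average has a median post-onset
  SEM/mean under 15%, the precision quoted for the experimental traces
  (measured ~7–9% overall; the dimmest 150 molecules·μm⁻² bin runs
  ~13%). Identical seeds give identical datasets.
* The log writer emits the ImageJ-macro dialect (per bead: one
  `area,ras_mean,perimeter,` line, one `value,` line per timepoint, then
  `!`), lossless under the package's parser. The optional image renderer
  draws non-overlapping uniform disks (constant Ras channel, time-varying
  effector channel) with the same noise model; photobleaching, stage
  drift and illumination gradients are intentionally absent, so the
  registration/rolling-ball steps of real pipelines are not modelled.

What passing these tests shows — and does not: the pipeline recovers what
the generator encodes (linear gain, lognormal bead spread, Gaussian
read noise). Real bead data have correlated noise, focus drift and
non-disk morphology that the generator does not emulate, so pipeline
performance there is a separate question.

## Processing pipeline

Traces are divided by the bead perimeter and zeroed at t₀ (both channels
are perimeter-normalised; whether the original analysis divided both or
only the effector channel is ambiguous, and the choice only rescales the
Ras axis). Beads are binned via the density chain above; bins average
pointwise with SEM = sd/√n (sample sd, per timepoint). The particle
detector thresholds (Otsu by default — the original macro used a
camera-specific hard-coded pair, so the threshold is exposed), labels
8-connected components, excludes border-touching components, and filters
by area ∈ [400, 15000] px² and circularity 4πA/P² ∈ [0.60, 1.00]
(ImageJ's convention; the estimate is clipped at 1 where digitisation
pushes it slightly above).

## Problem sizes

Defaults used throughout the tests and the acceptance script: 42000 s
horizon at 900 s sampling; 96-configuration scans; 15 beads per bin
(6 bins, 90 beads) for synthetic datasets; 100 random parameter draws for
the two-state no-overshoot property; oracle comparisons over 3600 s.
These are the study's own scales — single simulations take tens of
milliseconds, a full scan about a second.
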