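# Methods

## The model

`fsmotion` validates the Fujimura–Sugihara (FS) motion model for sprinting
players. The model is the equation of motion of a point mass driven by a
constant-magnitude force along a unit direction n̂ against viscous
(speed-proportional) resistance:

    m ẍ(t) = F n̂ − k ẋ(t).

Only two parameter combinations are identifiable from position data — the
kinetic parameters α = k/m (1/s) and V_max = F/k (m/s) — and with x(0) = 0,
ẋ(0) = v₀ the solution is

    x(t) = A(α, t) v₀ + B(α, V_max, t) n̂,
    A(α, t) = (1 − e^{−αt}) / α,
    B(α, V_max, t) = V_max (t − A(α, t)).

Sweeping n̂ over all directions places the arrival points after exactly t
seconds on a circle with centre A·v₀ and radius B — the *arrival circle*.
Two consequences drive the whole validation: the circle centre's
x-coordinate is strictly proportional to the initial speed (coefficient A),
and its radius is independent of the initial speed.

## The estimation procedure

Given per-frame tracking positions in contiguous play segments:

1. **Velocity** is the backward difference over a 1 s lag,
   v(t) = (x(t) − x(t−1)) / 1. No smoothing is applied; this is the
   estimator tracking-data studies use, and downstream binning absorbs
   noise.
2. **Velocity-frame heat maps.** For every player and frame t with defined
   velocity (goalkeepers excluded — they rarely sprint), the position at
   t + Δt is translated so the player sits at the origin and rotated so
   v(t) points along +x. Points are accumulated per initial-speed bin
   [v₀, v₀ + 0.3) m/s into square cells of side 0.2·Δt m anchored at the
   origin (half-open cells [i·s, (i+1)·s); boundary points go to the higher
   index).
3. **Isolation filter.** Occupied cells with fewer than c occupied Moore
   neighbours are removed in a single pass (neighbour counts from the
   unfiltered grid). c defaults to 8 for Δt < 1 s, 6 for 1 ≤ Δt ≤ 3 s, 4
   for Δt > 3 s. "Fewer than c" is implemented as *at least* c neighbours
   to survive: with c = 8 a strictly-more-than reading is unsatisfiable in
   a Moore neighbourhood, so the inclusive form is the only consistent one
   (`strict_adjacency=True` switches to strictly-more-than for c ≤ 7).
4. **Circle from extents.** Over surviving cell *centres* (using edges
   would bias the radius by half a cell),
   (x_c, y_c) = ((x_max + x_min)/2, (y_max + y_min)/2) and
   r_c = (x_max − x_min + y_max − y_min)/4.
5. **Inversion.** The through-origin least-squares slope of x_c on the bin
   midpoint v₀ over bins with lower edge ≤ 6 m/s (sparser, biased data
   above that) estimates A(α, Δt); α follows by bracketed root search
   (Brent on α ∈ [10⁻⁸, 10³]; A is strictly decreasing in α). The
   unweighted mean of r_c over the same bins estimates B, and
   V_max = r̄_c / (Δt − A(α̂, Δt)). The regression is constrained through
   the origin because the closed form forces a zero intercept; a
   free-intercept fit is available as a diagnostic only.

`ArrivalCircleModel.fit(delta_t)` packages steps 2–5 and returns a results
object with the per-bin circle table, delta-method standard errors (slope
SE propagated through dA/dα; radius SE through the B-inversion with α held
fixed — first-order only, correlations ignored) and a text `summary()`.

## Synthetic tracking generator

Real match tracking data are proprietary, so the pipeline ships with a
seeded generator that emulates their statistical structure:

- **Sampling**: 0.04 s frames in contiguous play segments; default six
  600 s segments (one hour) for 20 outfield players plus one goalkeeper.
- **Dynamics**: each player is a self-propelled particle obeying the FS
  equation with piecewise-constant parameters; within each constant-drive
  run the exact closed form is used (no integration error), so sprint
  intervals satisfy the model exactly before noise.
- **Behavioural states**: a three-state Markov chain — walk (terminal speed
  1 m/s), jog (3 m/s), sprint (8 m/s), all with α = 1.3 1/s, the reference
  sprint value. Default mean dwells 40/10/2 s with symmetric walk↔jog
  switching give ≈80/20/0.5% time occupancy, following time-motion studies
  in which standing/walking dominates and true sprinting is a small
  fraction of play; the low fast-state occupancy is also what keeps the
  long-lag MSD diffusive on a pitch-sized domain (below). The resulting
  speed histogram is bimodal with modes near 1 and 3 m/s and a decaying
  tail.
- **Direction**: the drive direction is redrawn after exponential run
  times (mean 10 s), reproducing straight runs of that order and hence the
  ballistic→diffusive MSD crossover. Turns are speed-limited (maximum
  deflection π·min(1, 1.5/v)): a walking player can reverse, a fast player
  cannot turn on the spot — uniform redraws at 5–8 m/s would be
  kinematically impossible motion and dominate the heat maps with
  artefacts. Entering the sprint state also redraws the direction (sprints
  are aimed at a fresh target).
- **Pitch**: 105 × 68 m. The free-space trajectory is folded into the
  pitch box by specular reflection (the triangle map per axis), which
  preserves straight-line character up to wall bounces; resampling
  directions near walls instead was found to truncate runs and visibly
  suppress the ballistic MSD exponent.
- **Noise**: isotropic Gaussian with stationary σ = 0.5 m, so ~95% of
  per-axis errors lie within the ±1 m accuracy quoted for optical
  tracking. The *generator default* is AR(1)-correlated error with a 15 s
  timescale: optical-tracking accuracy is an absolute, temporally smooth
  error, and frame-independent ±1 m jitter at 25 Hz would put ~0.7 m/s of
  noise on 1 s-lag velocities, erasing the observed walking-speed peak.
  White noise (`noise_correlation_time=0`) and a bounded uniform-disc
  model are available; `add_noise` itself defaults to white.
- **Goalkeeper**: one per dataset, walk/jog only, confined to a box near
  its goal line; role `GK` so analyses can exclude it.

`generate_sprint_ensemble` produces the idealized counterpart: n pairs of
(state at t, position at t + Δt) drawn exactly from the closed form for a
given (α, V_max, v₀, Δt), with drive directions evenly spaced on the circle
and optional Gaussian noise on the arrival point. It is the clean input for
validating the heat-map stages: the noise-free ensemble traces the arrival
circle exactly.

`GeneratorConfig.sprint_validation()` is a third regime used when probing
parameter recovery: players alternate long steady cruises at a
uniform-random target speed over the fitted v₀ range with full-drive
sprints in uniformly random directions.

### What the generator does *not* emulate

Players are independent (no ball, no tactics, no interactions); segments
have uniform length; behavioural switching is memoryless; turns are
instantaneous changes of drive direction; cruise speeds sit at three
discrete terminal values rather than a continuum. Passing tests on this
data therefore demonstrate the *pipeline arithmetic and geometry*, not that
real players obey the model — the latter is exactly what the original
analysis addressed with proprietary data.

## MSD analysis

For a play segment of length T, MSD(τ) = mean over all sampled start frames
t ∈ [0, T − τ] of |x(t+τ) − x(t)|² (the 1/(T−τ) prefactor in the defining
sum is read as that time average). The τ grid is log-subsampled multiples
of the frame interval up to T/2 (lags beyond half a segment are too noisy
to fit). Curves are averaged pointwise over players and segments, and the
scaling exponent β is the least-squares slope of log MSD against log τ
inside a stated window: β = 2 is ballistic, β = 1 diffusive.

On the default synthetic match (fixed seed 0) the fitted exponents are
β ≈ 1.84 over τ ∈ [1, 8] s and β ≈ 0.86 over τ ∈ [20, 100] s — the
crossover at the ~10 s run timescale. Two ceilings are worth recording.
With exponential run times of mean 10 s the velocity autocorrelation decays
as e^{−τ/10}, which caps the fitted short-window exponent near 1.91 even
for a single-speed walker in free space; wall bounces and the walk/jog
speed mixture decaying within the window cost a further ~0.07, so ~1.84 is
the honest value for this design, slightly below a strict 2 ± 0.15 band
but inside 2 ± 0.2. At long lags the pitch bounds the MSD at the
confinement scale 2(Var x + Var y) ≈ 2.6·10³ m², which is why the default
occupancy keeps mean squared speeds low; configurations with realistic
jogging/sprinting shares of instantaneous speed but *coherent* runs
saturate the MSD inside the [20, 100] s window and push β toward 0.5.

## Recovery limits of the extent estimator

The pipeline recovers parameters cleanly in the regime it was designed
for: on noise-free sprint ensembles the circle estimate is exact to one
cell, and the exact-circle round trip through `estimate_params` returns
(α, V_max) to 10⁻⁶. On behaviourally realistic match data, however, two
structural effects bias it, and both are properties of the method, not of
an implementation:

1. **Lagged-velocity misassignment.** The 1 s backward difference equals
   the instantaneous velocity only for quasi-steady motion. Every window
   that straddles a turn, a sprint onset or a deceleration is filed under
   a wrong initial velocity; from the window start the motion still follows
   the closed form, so the point lands on the arrival circle of
   v_inst ≠ v̄, displaced by A·|v_inst − v̄| (up to several m/s during
   events).
2. **Extents take maxima.** Any contamination that stays dense enough to
   survive the isolation filter sets the extents. Aligned acceleration
   streaks (sprint onsets along the current heading) are concentrated and
   survive; with frequent events the misassigned windows form an envelope
   that dwarfs the true circle (r_c → ~2B); with rare events the true
   boundary ring itself falls below the filter threshold and the extents
   collapse onto the dense steady-motion core. The noise halo of a dense
   region likewise pushes the surviving extent outward by an amount that
   grows with the point count.

Consequently the end-to-end recovery checks on the synthetic match (sprint
α = 1.3, V_max = 8) do not reach 10% accuracy at Δt = 1 or 2 s under any
event rate we consider physically defensible, and the corresponding tests
are expected to fail; they are kept at their stated tolerance rather than
weakened. The published analysis carries the same signature on real data:
a terminal speed estimate of 14.53 m/s at Δt = 1 s against the ~7.8 m/s
measured in sprint experiments, decreasing with Δt — flagged there as
noise sensitivity at small Δt. The same mechanism explains why the noisy
ensemble reconstruction of the Δt = 1 s mean radius comes out ~10% low at
720 directions per bin (the c = 6 filter decimates a one-observation-thick
smeared ring) while the Δt = 2 s radius, with its coarser 0.4 m cells, is
reproduced to under 1%.

## Numerical choices

- A(α, t) is computed as `-expm1(-αt)/α`, accurate through the α → 0
  limit; the inversion brackets may probe α near zero.
- `invert_alpha` uses Brent's method on [10⁻⁸, 10³] with xtol 10⁻¹²; the
  solution satisfies |A(α̂, t) − slope| < 10⁻⁹.
- The ODE integrator is classical fixed-step RK4 (default dt 10⁻³ s,
  configurable); against the closed form it is accurate to ~10⁻¹² m over
  10 s at dt = 10⁻⁴. A fixed step keeps runs bit-reproducible; the
  variable-coefficient extension m ẍ = F(t) n̂(t) − k(t) ẋ is integrated
  with the same scheme, with the direction re-normalized at every
  evaluation (user-supplied callables).
- Heat-map grids store integer counts with origin-anchored index offsets;
  empty selections yield a valid empty grid, and circle estimation on an
  empty grid raises.
- Problem sizes: tests and the acceptance script use the one-hour,
  20-player default match and 720-direction ensembles per bin — large
  enough that binomial noise on the fitted exponents is ≈0.01 and circle
  estimates are cell-limited.

## Known limitations

- The estimator biases above mean fitted (α, V_max) from match-like data
  describe the *envelope of displacements*, not the sprint law; treat them
  as descriptive parameters at a given Δt, as the Δt-dependence analysis
  does.
- The generator's behavioural parameters were calibrated once against the
  published observables (bimodal speed modes, MSD crossover) and are not
  per-test knobs.
- Standard errors in the results object are first-order propagation only.
- `simulate_ode` is for forward simulation; fitting time-dependent F(t),
  k(t) schedules to data is out of scope.
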