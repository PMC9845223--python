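# fsmotion

Validation toolkit for the **Fujimura–Sugihara (FS) sprint motion model**
on player tracking data. It is aimed at sports-analytics researchers and
movement scientists who work with optical tracking feeds (per-frame pitch
coordinates at 0.04 s) and want to test, on their own data or on synthetic
data, whether player sprints follow the viscous-resistance equation of
motion — and to estimate the model's kinetic parameters directly from
tracking data rather than from dedicated sprint experiments.

## The model

A player of mass m driven by a constant-magnitude force F along a unit
direction n̂ against speed-proportional resistance k obeys

```
m ẍ(t) = F n̂ − k ẋ(t)
```

with closed-form solution (x(0) = 0, ẋ(0) = v₀)

```
x(t) = A(α, t) v₀ + B(α, V_max, t) n̂
A(α, t)        = (1 − e^{−αt}) / α
B(α, V_max, t) = V_max (t − A(α, t))
```

where α = k/m (1/s) and V_max = F/k (m/s) are the identifiable *kinetic
parameters*. Sweeping n̂ over all directions puts the arrival points after
exactly Δt seconds on the **arrival circle**: centre A·v₀, radius B. The
validation pipeline builds velocity-frame heat maps of observed arrival
points per initial-speed bin [v₀, v₀+0.3) m/s, strips isolated cells,
estimates each heat map's boundary circle from its extents, and inverts

* the through-origin slope of the circle-centre x-coordinate on v₀ → α,
* the mean circle radius → V_max.

Because real match feeds are proprietary, the package includes a seeded
synthetic tracking generator (bimodal walk/jog speed structure, ~10 s
straight runs, FS sprints, ±1 m optical noise) so the entire pipeline runs
and is testable offline.

## Worked example

Estimate kinetic parameters from idealized sprint ensembles (720 sprint
directions per speed bin, drawn exactly from the closed form with
α = 1.23 1/s, V_max = 14.53 m/s):

```python
import numpy as np
import fsmotion as fm
from fsmotion.motion import KineticParams
from fsmotion.synthetic import generate_sprint_ensemble

params = KineticParams(alpha=1.23, vmax=14.53)
rng = np.random.default_rng(0)
ensembles = [
    generate_sprint_ensemble(params, v0=0.3 * i + 0.15, delta_t=1.0,
                             n_directions=720, rng=rng)
    for i in range(21)
]
model = fm.ArrivalCircleModel(ensembles, c=0)   # no isolation filter needed: clean data
res = model.fit(delta_t=1.0)
print(res.summary())
```

prints

```
FS arrival-circle kinetic parameter fit
=======================================================
delta_t:                   1.000  s
v0 bins used:                 21  (v0 <= 6 m/s)
slope A(alpha, dt):       0.5739  +/- 0.0023  s
alpha:                    1.2366  +/- 0.0099  1/s
mean r_c:                 6.1357  +/- 0.0051  m
vmax:                    14.3983  +/- 0.0119  m/s
=======================================================
```

The fitted slope is A(1.23, 1) = 0.575 to half a grid cell, α and V_max
come back within 0.5–1% of the generating values (the residual is the
0.2 m cell quantization), and `res.circles_frame()` holds the per-bin
circle table — radius ≈ 6.15 m in every bin, as the model demands
(B does not depend on v₀).

The same interface accepts a `TrackingDataset` (from
`fsmotion.io.read_tracking` or `fsmotion.generate_dataset`), in which case
heat maps are accumulated over all players and frames, goalkeepers
excluded, with the isolation filter applied.

Command-line equivalents:

```
fsmotion simulate --seed 1 --out match.csv
fsmotion msd match.csv
fsmotion estimate match.csv --delta-t 1
fsmotion report match.csv --delta-t 1 --delta-t 2 --out results/
```

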