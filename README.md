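# vpsolenoid

Design and quasi-static simulation of **variable-pitch solenoid RF coils**
for small-bore MRI (e.g. a dedicated finger coil at ultrahigh field).

A regular solenoid produces a transmit field B1 that sags toward the coil
ends: useful axial coverage is lost exactly where the anatomy of interest
may sit. Winding the coil **denser at the edges and sparser in the
centre** compensates for this. `vpsolenoid` parametrizes such windings,
simulates their B1 field with the Biot–Savart law, scores homogeneity and
sensitivity over the inner coil volume, and grid-searches the winding
parameters.

## Model

Each half of the winding (measured from the coil end inward, in winding
angle θ) has three segments controlled by two angles **α** and **β**:

* θ < α — **zero pitch** (a flat end ring),
* α ≤ θ < α + β — pitch **ramps linearly** from 0 to p_c,
* θ ≥ α + β — **constant pitch** p_c, as in a regular solenoid,

mirrored about the coil midplane. The plateau pitch
p_c = (L/2) / (Θ_half − α − β/2), with Θ_half = 360°·n/2 for n turns,
is the unique value for which the winding spans the full length L.
α = β = 0 recovers the regular solenoid.

Because the coil is small compared with the RF wavelength, B1 is computed
quasi-statically by summing the Biot–Savart contributions of the
discretized conductor polyline (midpoint rule):

    B(p) = (μ₀ I / 4π) Σₛ Δlₛ × (p − mₛ) / |p − mₛ|³

For each candidate (α, β), **sensitivity** is the mean B1 amplitude and
**homogeneity** the (population) standard deviation of B1 over a
cylindrical region of interest inside the bore; the scale-free
coefficient of variation std/mean ranks geometries, restricted to the
Pareto front of (std ↓, mean ↑).

## Worked example

The reference design — 34 mm winding diameter, 3 turns, 56 mm winding
length, 1 A — with optimized segment angles α = β = 80°:

```sh
$ vpsolenoid profile --outdir run0            # regular solenoid (α = β = 0)
dropoff = 0.4396 (edge B1 = 56.0% of centre)

$ vpsolenoid profile --config examples/finger_coil.yaml --outdir run80
dropoff = 0.2192 (edge B1 = 78.1% of centre)  # α = β = 80°
```

The **edge dropoff** is 1 − B1(±L/2)/B1(0) along the central axis: the
variable pitch lifts the edge field from 56% to 78% of the centre value.

The full design sweep (19 × 19 grid of α, β ∈ {0°, 10°, …, 180°}, 361
geometries, ~1 min on one CPU):

```sh
$ vpsolenoid optimize --config examples/finger_coil.yaml --outdir sweep
selected (alpha, beta) = (0, 180) by rule min-cv-on-pareto
```

`sweep/grid_surface.csv` holds the full metric surface
(`alpha_deg,beta_deg,mean_B1_T,std_B1_T,cv,n_points`) for heat-map
plotting; `sweep/optimum.json` records the selected pair and the rule.
The CV surface is very flat near its optimum (the best ~100 geometries
lie within ~1.5% of each other), so the selected pair should be read
together with the surface, not as a sharp argmax; the methods note
(`docs/methods.md`) discusses how the selection depends on the ROI and
on the B1 definition.

Other subcommands: `build` exports the conductor polyline as CSV,
`field` evaluates the full ROI field map (CSV and/or NIfTI volume).
Every run writes its fully resolved configuration and a log beside its
outputs; re-runs are bit-identical.

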