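# Methods

## The design problem

A solenoid receive/transmit coil wound at constant pitch has an axially
inhomogeneous B1: the field at the ends of the winding falls well below
the centre value, which costs excitation uniformity and signal near the
coil edges. Redistributing the winding — flat rings at the ends, a pitch
ramp, then a constant-pitch middle — trades a little central field for a
much flatter axial profile. `vpsolenoid` is the design loop for this
family of coils: geometry → field → metrics → grid search.

## Winding parametrization

One half-winding, in winding angle θ ∈ [0, Θ_half] measured from the coil
end (Θ_half = 360°·n_turns/2), has axial pitch

    p(θ) = 0                     θ < α        (flat end ring)
    p(θ) = p_c (θ − α)/β         α ≤ θ < α+β  (linear ramp)
    p(θ) = p_c                   θ ≥ α+β      (regular-solenoid middle)

The plateau value p_c = (L/2) / (Θ_half − α − β/2) is the unique constant
making the half-profile integrate to half the winding length L, so every
(α, β) candidate spans the same 56 mm and comparisons are fair. The
second half is the mirror image about the midplane; mirror symmetry of
the generated polyline is enforced to machine precision by construction
(the second half is the reflected first half). β = 0 is treated as the
limit of the ramp: an instantaneous step from 0 to p_c at θ = α. The
constraint α + β ≤ Θ_half keeps all three segments inside a half-winding.

The conductor is modelled as an infinitely thin filament along the strip
centerline. The fabricated coil uses 5-mm copper strip; a clearance check
warns when adjacent turn centerlines come closer than the strip width
(overlapping strips), but does not reject such geometries — extreme
flat-ring designs on the search grid legitimately stack turns.

Reference design parameters (defaults of `SolenoidSpec`): winding
diameter 34 mm (28 mm bore + 3 mm housing wall on each side), 3 turns,
winding length 56 mm, reference current 1 A, right-handed winding
starting at azimuth 0. Field magnitudes are invariant to winding sense
and start azimuth; they are fixed only so exported paths are
reproducible.

## Field computation

Quasi-static Biot–Savart summation over the polyline (midpoint rule,
second-order accurate in segment length), justified because the coil
(≈6 cm) is far smaller than the RF wavelength at typical Larmor
frequencies. The defaults discretize at 360 segments per turn (1°);
against the closed-form circular-loop field this is accurate to better
than 0.01%, and the convergence tests verify the expected ~4× error
reduction per halving of segment length. All internal units are SI
(m, T, A); the geometry layer accepts mm.

Evaluation points closer to a segment midpoint than half that segment's
length raise an error instead of returning a divergent midpoint-rule
value; silent garbage near the conductor would poison ROI statistics.

Two summation backends compute the identical sum: a compiled (numba)
kernel, used by default, and a chunked numpy path (`engine="numpy"`).
They agree to ~1e-14 relative and both are cross-checked in the tests
against a pure-Python double-loop reference.

### The B1 scalar

The coil-frame field vector must be reduced to a scalar "B1 amplitude"
per point. Three reductions are provided (`b1_proxy`):

* `magnitude` (default): |B|. Coordinate-free; inside a solenoid the
  field is dominated by the axial component, which is transverse to B0
  in use (solenoid axis ⊥ B0), so |B| is a faithful proxy there.
* `axial`: |B_z| in the coil frame.
* `transverse`: ½·√(B_y² + B_z²) — the rotating-frame B1+ amplitude of a
  linearly polarized coil for B0 along +x. The solenoid is nearly
  axisymmetric, so the azimuthal choice of the B0 direction is
  immaterial.

The default is the assumption-free choice; see "Sensitivity of the
optimum" below for where it matters.

## Metrics and region of interest

Sensitivity = mean B1, homogeneity = standard deviation of B1, over the
"inner coil volume": a cylinder of radius 14 mm (the housing bore) and
half-length 28 mm (the winding half-length), sampled on a 1 mm isotropic
grid (≈35k points). The population (not sample) standard deviation is
used — the grid exhaustively covers the ROI, it is not a random sample.
The coefficient of variation cv = std/mean is the scale-free ranking
quantity, so homogeneity is not conflated with overall field strength;
raw std is reported alongside. All ROI parameters are configurable, and
the full metric surface is always exported, because the location of the
flat optimum depends on them (below).

The axial **edge dropoff** is 1 − min(B1(+L/2), B1(−L/2)) / B1(0)
evaluated on the coil axis, with the edges at exactly ±L/2 (the winding
ends; "coil edge" is otherwise ambiguous). A dropoff of 0.45 means the
edge field is 55% of the centre value.

## Grid search and selection

The design sweep covers α, β ∈ {0°, 10°, …, 180°}² = 361 geometries.
"Optimal with respect to both homogeneity and sensitivity" is a
two-objective statement, formalized as the documented default rule
`min-cv-on-pareto`: restrict to the Pareto front in (std ↓, mean ↑),
then minimize cv, ties broken toward smaller α then smaller β. (For
strict domination the global cv minimizer is itself always on the front,
so `min-cv` selects the same design; both rules are provided, plus
`min-std-with-sensitivity-floor:<f>`.) The rule identifier is recorded
in every result file. The sweep is deterministic; repeated runs are
bit-identical.

## Sensitivity of the optimum (computed findings)

On the default ROI with the `magnitude` proxy the cv surface is very
flat: the best ~100 of 361 geometries lie within ~1.5% of each other
(cv 0.2214–0.2246). The rule selects (α, β) = (0°, 180°) — a pure
ramp-then-constant winding — while the fabricated design (80°, 80°)
has cv 0.2246 and sits within 0.2% of the Pareto front (it is dominated
by exactly one grid point, (110°, 10°), by 0.19% in mean and 0.004% in
std). Under the `transverse` (B1+) proxy, (80°, 80°) is itself
Pareto-optimal. Both (80°, 80°) and the cv minimizers improve markedly
on the regular solenoid (cv 0.2367, dropoff 0.44): the axial dropoff of
(80°, 80°) is 0.219. In short, the qualitative design conclusion —
variable pitch with dense edges beats constant pitch on both dropoff and
volumetric homogeneity — is robust; the exact argmax within the flat
basin depends on the ROI extent and the B1 definition, which is why the
package always exports the full surface rather than just the winner.

## Numerical choices

* Discretization: 360 segments/turn default (≥8 enforced); the polyline
  has n_turns·segments_per_turn + 1 vertices (1081 for the reference
  coil).
* Exclusion distance: half the local segment length (configurable
  factor).
* Axis profiles default to 57 samples over [−L/2, +L/2]; an odd count
  samples z = 0 exactly, as the dropoff statistic requires. The centre
  sample is accepted within half a grid step of z = 0.
* ROI sampling keeps lattice points with x² + y² ≤ r² (boundary
  included, with a 1e-9 mm² tolerance against roundoff) and orders them
  z-major, then y, then x, so outputs are reproducible byte-for-byte.
* Ties in selection rules break toward smaller α, then smaller β —
  fixed, documented, deterministic.
* μ₀ is taken from scipy.constants (post-2019 SI value).

## Scope and limitations

The quasi-static filament model captures the geometric design problem
but not: finite strip width and current redistribution (skin/proximity
effects), dielectric or sample loading, self-resonance, tuning/matching,
SAR, or any full-wave behaviour — those require an EM solver and a body
model and are deliberately out of scope. Consequently the simulated
absolute field amplitudes are per-ampere idealizations; the design
quantities of interest here (relative dropoff, cv, the shape of the
metric surface) are the quantities the model is suited to rank.
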