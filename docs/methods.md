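# Methods

This note documents the model behind `tkrsim`, its assumptions, the
parameters that matter, and what the synthetic geometry does and does not
emulate.

## Modelling reduction

The package emulates a hardware-in-the-loop knee rig — a robot moving and
loading physical implant components under the command of a musculoskeletal
model — as a *continuation of quasi-static equilibria*.  The emulated load
case is passive flexion/extension of a seated subject: motion is slow and
inertial forces are negligible, so each prescribed flexion step is solved
as a static balance.  This is the central reduction: the rig's two control
loops become, per step,

* position loop → flexion is prescribed;
* force/torque loop → the five constrained degrees of freedom (AP, SI, ML
  translation; adduction; internal rotation) are driven to equilibrium
  between implant contact loads and musculoskeletal loads.

Real-time robot dynamics, sensor/control latency and the physical rig's
compliant support are out of scope; their observable effect (small
repetition-to-repetition variability) is emulated by optional seeded
Gaussian perturbations of the fed-back degrees of freedom (defaults
0.01 mm / 0.01°, off unless enabled).

## Bodies, frames, load case

Right knee.  Body frames: x anterior, y proximal, z lateral; mm, N, deg at
all interfaces (radians internally).  The femur frame is the world frame
(femur fixed).  Seated posture: the femoral anterior axis points upward,
so gravity acts along −x with the shank+foot weight (6.1 % of the 80 kg
default subject ≈ 4.88 kg) at a centre of mass 250 mm distal to the knee.
The ankle is fixed (tibia+fibula+foot is one rigid unit).  The patella is
a one-degree-of-freedom body on a femur-fixed path (below).  Tibiofemoral
motion is parameterized directly in the Grood–Suntay convention (flexion
about the femoral ML axis, axial rotation about the tibial long axis,
adduction about the floating axis; internal rotation and adduction
positive), so solver outputs are the reported clinical kinematics with no
further conversion.

## Parametric implant surrogate

The commercial implant geometry used by hardware rigs is proprietary, so
the package generates a documented parametric surrogate of a symmetric
bicondylar multi-radius CR design:

* **Femoral component** — each condyle is a channel surface: a coronal
  circle (radius 15 mm) swept along a sagittal spine made of a distal arc
  (surface radius 35 mm) blending tangentially into a posterior arc
  (22 mm), condylar planes at z = ±22 mm.  The construction provides an
  *exact* signed-distance field (distance to two planar arcs minus the
  coronal radius), which is what makes the contact evaluation fast and
  smooth enough for Newton iteration.  The posterior-arc centre of each
  condyle is recorded as that condyle's flexion facet centre (FFC); for a
  circular posterior facet this is identical to the circle-fit definition
  used on anatomical or scanned implants.
* **Tibial insert** — two dished compartments, sum-of-sagittae surface
  with sagittal radius 60 mm and coronal radius 22 mm (non-conforming:
  both exceed the femoral radii), 10 mm thick, tilted by the built-in
  posterior slope of +7° about the ML axis.  Each compartment is meshed as
  a closed solid; only the dish faces are contact-carrying.

Slope and axial-rotation offsets are applied to the insert pose (slope
first, about the tibial ML axis; then axial rotation, about the tibial
proximal axis; both through the insert centroid).  Positive slope =
posterior-distal tilt; positive rotation = internal rotation of the
component.  Whether a real study varies slope by re-cutting the tibia or
by component pose cannot be distinguished from outcome curves;
component-pose tilt is implemented.

What the surrogate does **not** model: bone surfaces, cartilage/menisci,
cement interfaces, implant sizing, and any subject-specific geometric
detail.  Results are design- and configuration-specific in the same way a
single-specimen hardware study is.

## Soft tissue

**Ligaments** are straight-line tension-only bundles with the standard
slack/quadratic-toe/linear law (`eps_l = 0.03` unless configured
otherwise); stiffness is N per unit strain.  Ligament wrapping is
deliberately absent.  The implanted inventory (16 tibiofemoral + 9
patellar bundles; ACL only in the native option) and all attachment
coordinates, stiffnesses and slack-length rules live in
`src/tkrsim/data/defaults.yaml` and can be replaced wholesale via the
ligament CSV interface.

Reference (slack) lengths are specified by *rules* rather than absolute
numbers, because no consistent table of attachment coordinates and slack
lengths exists for a generic parametric knee: either a prestrain at the
10°-flexion nominal pose (`prestrain_ref`) or the flexion angle at which
the bundle becomes taut under a nominal kinematic sweep
(`engagement_deg`).  Two posterior-capsule bundles carry explicit
reference lengths calibrated against the reference model's equilibrium
kinematics instead, because their function (terminal-extension restraint)
depends on equilibrium, not nominal, kinematics.

The default anatomy was calibrated, by iterating the model's own
equilibrium solutions, to reproduce the qualitative behaviour expected of
a CR-TKR without ACL and menisci: collaterals near-isometric and tightest
near extension; PCL slack below ≈30° and the dominant tension carrier in
deep flexion; posteromedial capsule and crossing posterior-capsule fibres
engaging only near full extension, supplying both the steep hyperextension
force rise and the external-rotation (screw-home) torque in terminal
extension; a laterally placed tibial tuberosity so that component rotation
modulates extensor-mechanism tension with the clinically reported sign.
Two deliberate departures from textbook anatomy are documented here: the
oblique posterior-capsule (OPL) bundles run from the posteromedial femur
to the posterolateral tibia (the mirrored course produced an
internal-rotation torque in terminal extension in this geometry), and the
deep-MCL bundles are placed near-isometric rather than anterior (anterior
placement made them unphysiologically taut in deep flexion).

**Quadriceps**: four heads (RF, VI, VM, VL) with a constant 120 N total,
split equally by default (configurable).  Paths wrap over a femur-fixed
trochlear ellipsoid; wrapping uses a tangent-arc via-point construction in
the affinely scaled (unit-sphere) space of the ellipsoid — exact for
spheres, a good approximation of the geodesic for the moderate
eccentricities used here.  Muscle wrenches satisfy action–reaction exactly
(the obstacle body receives the negated sum of the end-point wrenches).

**Patella**: rides a femur-fixed circular arc (radius 45 mm about the
condylar centre), with path angle mapped linearly to flexion
(phase −30°, gain 1.0) — these two constants were calibrated once so that
the patellar ligament is near-isometric (±3 %) over the flexion arc,
playing the role of the precalibrated patella path a hardware study would
obtain from a prior contact simulation.  A tabulated path (CSV of flexion,
position, orientation) can be substituted.  The patella only routes the
extensor mechanism; no patellofemoral contact force is computed.

## Contact

One-sided elastic (Winkler) foundation on the insert: element pressure
`p = k_c·depth` at the element centroid, force along the element normal,
no shear coupling.  Default `k_c = 30 N/mm³` — the order of the UHMWPE
elastic modulus (~1 GPa) divided by a ~30 mm effective layer/backing
scale; it is a surrogate parameter, configurable, not a literature value.
Penetration depth is the signed distance of the centroid into the femoral
solid (exact for the parametric component; nearest-point queries via
trimesh for arbitrary meshes).  The convention "depth into the solid,
force along the insert normal" matches the closed form
`F = k_c·π·R·δ²` for a rigid sphere on a flat layer to well within the
mesh discretization error (the acceptance suite verifies 2 % and 1 %
refinement convergence).

Friction is Coulomb sliding with `μ = 0.04` (CoCr on UHMWPE): each loaded
element receives `μ·p·A` along the tangential direction of the femoral
surface velocity induced by the flexion rate; the resultant torque about
the flexion axis is the "resisting torque" a rig's force-torque sensor
measures.  Friction power is non-positive by construction, and produces
the expected flexion/extension hysteresis; with `μ = 0` forward and
backward sweeps coincide.

A penetration cap (2 mm) guards the solver: exceeding it signals gross
interpenetration (e.g. subluxation) and surfaces as a flagged step error
rather than a silent bad solution.

## Solver

Damped Newton on the five constrained dofs: forward-difference Jacobian
(step 1e-4 mm/deg), truncated-least-squares step (`rcond = 1e-10`, which
yields the exact Newton step for well-conditioned Jacobians and a
minimum-norm step along indifferent directions such as axial rotation of
a rotationally symmetric toy joint), step cap 3 mm/deg per iteration,
step-halving line search, max 50 iterations, convergence at residual norm
< 1e-3 N / N·mm.  Movements run as continuations with warm starts and a
linear predictor; a failed warm start is retried once from the geometric
(nominal-pose) initial guess.  Tolerances are engineering choices; the
spring-only and sphere-in-dish oracles confirm 1e-8 mm agreement with
analytic roots and 2 % agreement with the foundation closed form.

## Outcome metrics

* **Joint state**: Grood–Suntay decomposition; recomposing the pose from
  the decomposed state reproduces it to 1e-9.
* **Femoral rollback**: AP position of the femur in the tibia frame,
  posterior negative, reported relative to the first step of the
  movement (the zero-reference choice is a convention; absolute AP is
  also in the trace).
* **FFC tracks**: the condylar posterior-arc centres transformed into the
  insert frame; the AP coordinate is the per-compartment rollback.
* **Screw-home**: net external rotation over the terminal 20° of an
  extension movement, detected above a 0.5° threshold.  Window and
  threshold are package conventions; the phenomenon itself has no
  standard numeric criterion.
* **Paradoxical anterior translation**: flexion sub-ranges where the
  medial FFC moves anteriorly with increasing flexion (1e-6 mm hysteresis
  guard); the upper bound of the anterior-moving range is reported.
* **RMSE**: per-metric root-mean-square difference against the reference
  configuration on the common flexion grid (linear resampling if grids
  differ).

## Study driver

The default matrix is the single-factor design: reference
(flexion + extension), tibial rotation ±3°/±6° (flexion), tibial slope
−3°/+3° (flexion + extension) and +6° (flexion), PCL resection (flexion);
flexion 10°→120°, extension 60°→−10° (10° hyperextension), 1° steps,
three repetitions.  The reference run is computed once and reused for all
comparisons.  Factorial combinations are deliberately not part of the
matrix (single-factor design); `build_variant` changes exactly one
parameter per variant.

The rotation-direction effect (internal rotation raises, external
rotation lowers, the tibiofemoral contact force) is assessed on the mean
contact force over the flexion grid.  In this surrogate the effect is
pointwise through mid-flexion but crosses over above ≈100° flexion, where
dish/soft-tissue rotational wind-up around the medial-pivot pattern
dominates; the range-mean is the faithful summary of the directional
claim.  The slope ordering (−3° ≥ reference ≥ +3°) and the PCL-resection
effects hold pointwise.

## Problem sizes and determinism

Default meshes: ~8.3k femoral triangles, ~2.6k insert articular elements
(1.5 mm target edge).  A full default study is ~3,300 equilibrium solves
and runs in a few minutes on one CPU.  With noise off, repetitions are
bit-identical and all repetition SDs are exactly zero; with noise on, the
entire study result is a deterministic function of the study seed.
Development checks in this repository use coarser steps (5–25°) where the
full 1° resolution adds nothing to the property under test; the
acceptance checks run the complete 1°-step matrix.

## Known limitations

* The surrogate anatomy is *one* plausible CR knee; absolute force and
  kinematic magnitudes are configuration-specific.  Passing the
  directional checks shows the mechanisms are represented, not that any
  specific patient or commercial implant is reproduced.
* Quadriceps force is constant (passive load case); no activation
  dynamics, no Hill-type behaviour.
* Ligaments are straight lines without wrapping; viscoelasticity and
  damping are absent (the quasi-static solver needs none).
* No patellofemoral contact mechanics; the patella path is fixed, so the
  extensor mechanism cannot respond to component rotation by patellar
  maltracking.
* The elastic foundation has no shear coupling, no Hertz-type stress
  recovery, and is not suitable for wear or edge-loading stress analysis.
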