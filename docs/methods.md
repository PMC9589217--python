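# Methods

`femsgait` is a desk-scale concurrent finite-element musculoskeletal
(FE–MSK) framework for the stance phase of walking. It couples a
rigid-body lower-limb model — inverse kinematics, inverse dynamics and a
cubed-activation static muscle optimization — with a deformable contact
model of the tibiofemoral joint, and uses the coupled model to compare
an intact knee against medial-meniscus radial tears (33/50/83% of the
local width at the anterior horn, midbody and posterior horn) and total
medial meniscectomy under identical gait input. This note records the
models, the parameter choices that matter, and what the synthetic study
conditions do and do not represent.

## Coordinate and unit conventions

Right-handed frame, right leg: X anterior, Y superior, Z lateral
(medial = −Z). Lengths in mm, forces in N, moments in N·mm, stresses
and moduli in MPa, masses in kg, angles in rad. Bodyweight (BW) is
subject mass × 9.81 m/s².

## Synthetic study conditions

No measured subject data ships with the package; every input is
generated.

**Subject.** Mass 80 kg, height 1.75 m (the study conditions). Segment
masses, lengths, centres of mass and gyration radii are standard
anthropometric fractions of mass and height
(`femsgait/data/anthropometry.yaml`).

**Gait trial.** Marker trajectories (100 Hz) and ground reaction force
(1000 Hz) for one stance phase of 0.65 s. The kinematic template is
built from the planted foot upward: the foot is flat with a late heel
rise pivoting about the toe, the shank rolls forward over the ankle
(−12° → +34° tilt), the knee traces the loading-response flexion wave
(~18° at 22% stance) plus pre-swing flexion (~34° at toe-off), and the
pelvis pose is whatever closes the chain with a level pelvis. Hip
flexion (≈ +25° → −16°) and forward progression (≈ 1 m/s) therefore
*emerge* rather than being prescribed, and the support foot is exactly
stationary — the property that keeps the inverse-dynamics moments
physiological. The vertical GRF is a double-hump curve (1.10 BW weight
acceptance at 25% stance, 0.75 BW mid-stance valley, 1.05 BW push-off at
75%), the anterior-posterior shear is ±0.14 BW braking/propulsion, and
the centre of pressure runs heel to toe with a 10 mm medial offset
(the frontal alignment that gives the knee a modest adduction moment).
Gaussian marker noise (default 0 for the study conditions) is seeded.

What the trial does *not* emulate: soft-tissue artefact, marker
occlusion patterns, mediolateral GRF shear, bilateral/trunk dynamics,
step-to-step variability. Passing tests therefore demonstrate the
*pipeline's* correctness and the *relative* effect of meniscal lesions,
not subject-specific prediction.

**Knee geometry.** Femoral condyles are spherical caps (sagittal radii
25/24 mm medial/lateral + 2.2 mm cartilage offset) whose centres define
the flexion axis, so the contact surfaces are flexion-invariant
surfaces of revolution. The tibial cartilage is a 2 mm elastic slab per
compartment with a mildly dished (0.8 mm) superior surface; each
meniscus is a C-shaped swept wedge (270° arc, inner radius 10.5 mm,
outer 21 mm, wedge height 1.2–6 mm) of 8-node hexahedra whose superior
surface is cut congruent to the overlying condyle with a 1.8 mm
clearance. The clearance and dish depth set how load splits between the
direct femur–cartilage path and the meniscal path; the defaults were
chosen so the intact meniscus carries roughly 55–70% of the medial
load, the mid-range of published meniscal load-share estimates. Default
mesh: 18×4×2 elements per meniscus, 6×7×2 per cartilage slab (~700
hexahedra per knee, ~10⁴ displacement DOFs) — deliberately coarse so a
full variant matrix runs on one CPU in minutes. A refinement smoke test
shows the total femoral contact force changes well under 5% when the
mesh is refined ~3×; the meniscus/cartilage *partition* is more
mesh-sensitive, which is one reason comparisons between variants are
always made on the same mesh.

**Radial tears** delete elements of the intact medial meniscus mesh —
never remesh — in one circumferential element column at the configured
angular position of the sector, from the inner rim over
`round(width_fraction × n_rad)` radial rings (33% → 1 of 4, 50% → 2,
83% → 3). The deepest remaining ring of the column is tagged as the
tear tip; the same structured-grid tags address the matched elements of
the intact mesh so tip stresses are compared at identical locations.
Total meniscectomy removes the medial meniscus body, its horn
attachments, the transverse ligament and the medial meniscal contact
pairs.

## Passive structures

**Ligaments.** Seven structures (ACL, PCL, MCL, PMC, LCL, ALS, OPL) in
23 tension-only bundles with the piecewise force–strain law: zero below
slack, quadratic `k1 (l−l0)²` in the toe region (strain ≤ 2ε_l,
ε_l = 0.03), linear `k2 [l − (1+ε_l) l0]` beyond. The (k1, k2) table is
packaged data. The two branches need not meet continuously with the
tabulated constants; the law is applied literally and `branch_jump()`
reports the discontinuity per bundle. Slack lengths are calibrated at
full extension with shipped reference strains (ACL 0.04, PCL 0.01,
MCL/LCL 0.03, capsule structures 0.02): all-zero strains would let the
tibia slide several millimetres before any restraint engaged.

**Horn attachments.** Each horn face is tied to the tibia by one linear
spring per face node with `k = E a / (n l)` (E = 600 MPa, a = face
area), so the assembly reproduces the axial stiffness `E a / l` of a
uniform rod regardless of the spring count. The **transverse ligament**
is four springs of 12.5 N/mm total between the anterior horns.

**Capsule.** A lumped restraint of 25 N/mm on the tibial translations
(2.5×10⁵ N·mm/rad on the two free rotations) stands in for the joint
capsule and deep soft tissues that are not otherwise modelled; it is
within published knee anterior-posterior laxity stiffness and also
keeps the meniscectomised knee (which loses the meniscal conformity
restraint) numerically well-posed.

## Muscles and static optimization

Twenty Hill-type units (the gluteus maximus as 3 units, iliopsoas,
pectineus, the four quadriceps heads, three hamstrings plus the short
biceps head, both gastrocnemius heads, soleus, both tibialis muscles
and the long toe extensors) as via-point polylines with a
tangent–arc–tangent cylinder wrap on the gastrocnemii. Parameters
(attachments, Fmax, optimal lengths) are a literature-style editable
YAML fixture, scaled with height — the gait demands are producible with
two caveats inherent to this muscle list: it contains no strong hip
abductor or rotator, so a handful of stance frames (worst ≈ 11 N·m at
push-off) are genuinely outside the feasible set (see below).

Rigid tendon, no force–velocity term: force is
`Fmax [a f_act(ℓ̃) + f_pass(ℓ̃)]` with a Gaussian active curve (width
0.55) and a passive exponential engaging beyond 15% stretch. Because
the rigid tendon would put the whole musculotendon excursion on the
fibre, normalized length uses an effective optimal length floored at
20% of the reference path length, calibrated so ℓ̃ = 1 at a mid-stance
posture (hip 15°, knee 20°) — centring the operating range on the gait
excursions. Moment arms are tendon-excursion arms `r = −∂L/∂q`,
evaluated analytically from the motion of path points distal to each
DOF (wrap tangent points enter as material points of the host segment);
the test suite verifies them against central differences at 10⁻⁶ mm.

The activation problem — minimize Σ s³ subject to the five
generalized-moment equalities (hip flexion/adduction/rotation, knee
flexion, ankle) and 0 ≤ s ≤ 1 — is a smooth convex program solved by
SQP (SLSQP, row-normalized constraints, deterministic cold start
s = 0.1) with an interior-point-style trust-region fallback;
stationarity is verified post-hoc by a KKT residual. When the demand is
infeasible the solver reports it explicitly and returns a bounded
weighted least-squares solution that prioritizes the knee, ankle and
hip-flexion rows, so the unproducible frontal/transverse residual never
corrupts the sagittal balance that drives joint loading.

## Knee contact solve

The deformable bodies (two menisci, two tibial cartilage slabs) use
8-node hexahedra with mean-dilatation (B-bar) integration — volumetric
locking-free at ν = 0.46 with full deviatoric quadrature (no hourglass
modes). Cartilage is isotropic (E = 5 MPa, ν = 0.46); the meniscus is
transversely isotropic with the stiff axis along the per-element
circumferential fibre direction (E_c = 140 MPa, E_r = E_a = 20 MPa,
ν_in = 0.2, ν_out = 0.3); the out-of-plane shear modulus is not
determined by those constants and defaults to 10 MPa (configuration).
The femoral cartilage layer is carried geometrically but acts as a
rigid-backed master surface (condyle sphere + thickness offset): its
own compliance is omitted from the contact kinematics, a deliberate
desk-scale simplification. The patellofemoral pair is handled by the
extensor-mechanism muscle path (quadriceps via-point → patellar-tendon
insertion), not by an FE patella.

Contact is node-to-rigid-surface penalty (stiffness 400 MPa/mm of
tributary area, about 20× the confined-cartilage foundation stiffness,
giving residual penetrations of a few hundredths of a mm) with Coulomb
friction μ = 0.04 regularized over a 0.6 mm slip scale. The quasi-static
equilibrium in the five knee secondary DOFs (three tibial translations,
varus-valgus, internal-external rotation; flexion prescribed from the
primary kinematics) plus all elastic DOFs is found by Newton iteration:
Gauss–Newton contact Hessian, sparse factorization of the elastic block
with dense bordering of the pose DOFs, Armijo backtracking on the exact
potential, and an approach phase that starts the surfaces just engaged.
Friction, being non-conservative, is frozen as an external force and
updated in a short under-relaxed fixed point (3 passes); the residual
reported afterwards includes the live friction law. A solve is accepted
below 4 N residual (typical converged values are well under 1 N against
kN-scale loads) and aborts above 20 N.

Stress recovery is per-element centroid Cauchy stress; "shear stress"
is the Tresca/2 scalar (σ₁−σ₃)/2 (the full tensor is exported so other
scalars can be derived), and the hoop stress σ_cc is the projection on
the local circumferential axis, tension positive.

## The concurrent loop

Per stance time point (16 evenly spaced points, 0–100%): inverse
dynamics moments are fixed by the markers and GRF; the loop iterates
{muscle geometry at current e_s → static optimization → knee reaction
wrench from the distal free body (intersegmental load minus the muscle
forces crossing the joint, applied along their crossing line) → contact
solve → new e_s} with 0.5 under-relaxation on e_s, warm-starting each
time point from the previous one. Convergence requires the knee
flexion-extension moment produced by the solved activations, re-
evaluated with the moment arms at the contact-solved e_s, to match the
demand within 0.5 N·m (≤ 10 outer iterations; in practice 1–3).
Secondary kinematics feed back into muscle geometry and the reaction
wrench; their sub-millimetre effect on segment inertial kinematics is
neglected. A frozen-feedback ablation (e_s never fed back) is built in
and leaves a measurably larger knee-moment inconsistency.

Open design choices resolved here: the outer loop iterates per time
point with warm starts (not over the whole trajectory jointly); the
five equilibrium constraints live in one coupled program rather than
per-joint programs; the knee equality covers flexion-extension only,
with the remaining knee components balanced by contact, ligaments and
the capsule.

## Numerical parameters (defaults)

| parameter | value | why |
|---|---|---|
| penalty stiffness | 400 MPa/mm | ~20× foundation stiffness; penetration ≪ cartilage strain |
| friction μ / slip reg. | 0.04 / 0.6 mm | stated friction; regularization scale ≈ observed slip |
| contact residual tol | 0.2 N | ≪ smallest meaningful load change |
| outer-loop tol | 0.5 N·m knee moment | well under moment magnitudes (≈ 10–60 N·m) |
| outer-loop max iterations | 10 | observed 1–3 |
| pose (capsule) stiffness | 25 N/mm | published AP laxity range |
| angle filter / GRF filter | 6 Hz / 20 Hz low-pass, zero phase | standard gait processing |
| time points | 16 over stance | the framework's analysis grid |

## Known limitations

- Small-strain elasticity and a rigid-backed femoral master: contact
  pressures at high load are approximate; pressure *ratios* between
  variants are the reliable output.
- No biphasic/poroelastic or fibril-reinforced behaviour; no
  viscoelasticity, no ligament wrapping, no cartilage damage laws.
- Single synthetic subject and trial; absolute magnitudes depend on the
  parametric geometry (clearance, dish, radii) and should be read as a
  self-consistent model world, not as patient predictions.
- The muscle fixture's missing frontal/transverse hip actuators are a
  faithful property of the 20-muscle list; flagged infeasible frames
  are reported per time point in the summaries.
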