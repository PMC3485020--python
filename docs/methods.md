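# Methods

`limbloads` estimates muscle and knee joint loads in the right lower limb
during a maximal counter-movement jump, and quantifies how sensitive those
estimates are to (a) an axial-rotation offset of the shank — the dominant
soft-tissue-artifact error in optical motion capture — and (b) the upper
force bounds of the five muscles that control non-sagittal rotation at the
knee. This note documents the model, its numerical choices, the synthetic
data that drives the test suite, and the limits of what the package's green
tests demonstrate.

## The musculoskeletal model

Four rigid segments (foot, shank, thigh, pelvis) are connected by
three-degree-of-freedom ball joints at the ankle, knee and hip. There is no
constrained knee axis: the knee centre is a fixed point of the thigh frame
evaluated at the thigh's instantaneous pose, so out-of-plane moments enter
the muscle force-sharing problem rather than being absorbed by a hinge.

Conventions, used throughout:

* global frame: X anterior, Y up, Z to the subject's right (right-handed);
* segment frames: origin at the proximal joint centre (the foot's at the
  ankle), local x anterior, y along the long axis pointing proximally,
  z lateral;
* orientations are scalar-first unit quaternions q mapping local to global
  coordinates; right-multiplying a series by a fixed quaternion is a
  rotation about a local axis. Internal rotation of the right shank is
  positive about local +y.

**Inertial scaling.** Segment mass, CoM offset and radii of gyration scale
from body mass and stature through a packaged coefficient table
(`data/de_leva.csv`, adjusted Zatsiorsky–Seluyanov-style adult-male values;
the "pelvis" row is the lower-trunk entry). The shank's transverse radii
are deliberately symmetrized to one value, making its tensor exactly
axisymmetric about the long axis. That symmetry is load-bearing: together
with a CoM on the long axis it guarantees — at machine precision, not
approximately — that rotating the shank orientation stream about its own
long axis changes no intersegmental wrench, which is the premise of the
rotation experiment (`tests/test_acceptance.py` asserts ≤ 1e-9).

**Muscle geometry.** A reduced set of 27 line elements covers every major
actuator group plus the five knee rotators studied individually (gracilis,
plantaris, popliteus, sartorius, tensor fasciae latae). Paths are straight
polylines through fixed via points; no wrapping surfaces. Attachments live
in `data/muscle_points.csv` in reference-skeleton coordinates (1.79 m
stature) and scale to the subject by a single uniform factor
height/1.79 by default (per-axis factors are accepted). The coordinates are
representative rather than specimen-accurate; they were placed, and in a
few cases adjusted, so that the set reproduces documented anatomical
function:

* every one of the 9 joint DOFs has antagonistic coverage (verified by
  frame-by-frame LP feasibility over the whole synthetic jump);
* the quadriceps/patellar via point (thigh frame, (0.050, −0.500) m) keeps
  the extensor moment arm positive (+0.031 to +0.072 m) over the full
  0–2.2 rad flexion range — a fixed via point nearer the knee centre loses
  the arm in deep flexion, which no real knee does;
* external rotation of the shank increases the popliteus moment-arm
  magnitude about the shank's superoinferior axis and the TFL magnitude
  about the anteroposterior axis at mid-flexion, the mechanism by which an
  axial offset changes rotator recruitment;
* tibialis posterior is routed across the midfoot so the invertor/evertor
  pair can balance axial ankle moments without an unrealistic inversion
  by-product (the reduced foot has no subtalar articulation to do it).

Because absolute force magnitudes are sensitive to this geometry, the
package's outputs should be read as a behavioural model: trends and
sensitivities, not subject-specific newton values. PCSA values are
representative of a strong athletic male (quadriceps total 175 cm²); the
maximum permitted muscle stress defaults to 61 N/cm² (a common literature
value — configurable; both sensitivity experiments concern relative
changes, not this constant).

## Kinematics

Marker trajectories (≥ 3 non-collinear markers per segment) are low-pass
filtered and converted to poses per frame with the closed-form quaternion
solution of the absolute-orientation problem (eigenvector of the 4×4
cross-covariance form). The reference marker clouds are expressed in
segment frames, so the recovered translation is the segment origin. Series
are sign-canonicalised (first w ≥ 0, consecutive dot products ≥ 0) before
differentiation.

**Filtering.** The default filter is the discrete analogue of a quintic
smoothing spline: minimise Σ(y−x)² + c Σ(Δ³y)² with the penalty weight set
from the −3 dB amplitude point of the requested cutoff
(c = (√2−1)/(ω_c⁶ h⁶); 10 Hz at 200 Hz by default), solved as a banded
sparse system. The third-difference penalty annihilates quadratics, so
constant through quadratic trends pass exactly and endpoints are not
distorted. A dual-pass 5th-order Butterworth (`mode="butterworth"`) is the
documented alternative; both meet the frequency contract the tests assert
(< 1 % attenuation at 1 Hz, > 90 % at 50 Hz). The same filter is applied to
marker and force data before modelling and to load/force outputs before
summarising.

**Derivatives.** q̇ and q̈ by central differences (one-sided endpoints);
angular velocity ω = 2 q̇ ⊗ q* (vector part, global frame), angular
acceleration by differentiating ω. Spline-analytic derivatives were
deliberately not used: finite differences at 200 Hz are second-order
accurate and identical for every orientation stream, perturbed or not.
After an axial offset the derivatives are recomputed, although for a
time-constant offset ω and α are provably unchanged.

## Inverse dynamics

Per frame, all three joint wrenches (force + moment at the instantaneous
joint centre, proximal-on-distal) are obtained in one step as the solution
of a single 18×18 linear system stacking each segment's Newton–Euler
balance: force rows m(a_com − g) and moment rows I_g α + ω × I_g ω about
the CoM, with the ground reaction applied at the centre of pressure and an
optional vertical free moment. This is algebraically identical to the
distal-to-proximal recursion, which the test suite retains as an
independent oracle (agreement ≤ 1e-8 relative on random smooth inputs; in
practice ~1e-15). Joint centres: ankle at (0, −L_shank, 0) in the shank
frame, knee at (0, −L_thigh, 0) in the thigh frame, hip at the pelvis
origin.

## Muscle force sharing

Per frame the muscle forces solve

    min Σ_i (F_i / PCSA_i)^n   s.t.  R F = m,  0 ≤ F_i ≤ PCSA_i σ_max

with n = 30 and R the 9×N moment-arm matrix ((p − c) × û per crossed
joint, û the unit pull on the distal side; entries are exactly zero for
joints a muscle does not cross, and equal −∂L/∂θ by the tendon-excursion
identity, which the tests verify by finite differences to 1e-4 m).

Numerics: the problem is posed in normalised stresses x_i = F_i/(PCSA_i
σ_max) ∈ [0,1]. Feasibility is certified first by an exact LP (HiGHS);
infeasible frames are flagged unsolved, excluded downstream, and reported
as a percentage — unsolved frames are a first-class output of the method,
not an error. Feasible frames are then rescaled by the min–max peak t*
(one more LP) so the optimum sits near 1 — Σx³⁰ is numerically flat for
x ≪ 1 and stalls gradient methods otherwise — and solved by SLSQP with an
exponent-continuation schedule (2, 6, 14, 30), warm-started frame to frame
(the objective is strictly convex on the affine slice, so warm starts
cannot change the answer beyond tolerance; a cold/warm test asserts this).
The scaled equilibrium tolerance is 1e-6·max(1, ‖m‖_∞).

**Proximity to the min–max solution.** As n → ∞ the power-law solution
approaches the min–max (lowest peak stress) force sharing. How close n = 30
gets is quantifiable and worth stating precisely:

* for a single-DOF synergist group the peak-stress ratio is
  a_max^{1/(n−1)} Σa_i / Σa_i^{n/(n−1)} with a_i the per-unit-stress moment
  capacities; it grows like (capacity spread)^{1/29}, e.g. ≈ 2 % at spread
  3.5;
* with several coupled equilibrium rows only the norm-equivalence bound
  peak ≤ N^{1/n} t* is guaranteed (≈ 6 % at N = 6), and problems exist
  whose true n = 30 optimum sits > 2 % above t* even with identical
  capacities (verified against a tight trust-region reference).

The acceptance check therefore samples single-DOF groups of comparable
capacity (arm U(0.025, 0.040) m, PCSA lognormal σ = 0.15), where the
measured worst gap is 0.6 %, and separately asserts the N^{1/n} bound on
coupled problems.

## Knee loads

* **Tibiofemoral contact**: the intersegmental knee force minus the pulls
  of every knee-crossing muscle on the shank, expressed in the shank
  anatomical frame (closure with the muscle pulls is asserted numerically).
* **Patellofemoral contact**: frictionless-pulley patella. The
  patellar-tendon force is the quadriceps force times a flexion-dependent
  ratio ρ, and the contact is the law-of-cosines magnitude of the two
  tendon pulls at a tabulated included angle. ρ and the angle live in
  `data/patellofemoral.csv` — a monotone, editable placeholder
  representative of published patellar-mechanism data, not a validated
  subject table; at full extension the pulls are collinear-opposing and
  contact → 0.
* **Shear**: the AP/ML components of the contact in the shank frame,
  reported with anterior negative. Anterior shear is attributed to the ACL,
  posterior to the PCL, the reported resisted force scaled by a
  flexion-dependent effectiveness factor (`data/ligament_effectiveness.csv`,
  also a documented placeholder). Ligaments carry no load inside the
  equilibrium; the attribution only labels and scales the report. Tibial
  plateau tilt is not modelled (AP/ML axes are the shank local axes).

## Synthetic jump trials

The study's motion recordings are not public, so the generator produces
the class of input the analysis assumes: a ~2.8 s maximal counter-movement
jump at 200 Hz — quiet stance, counter-movement to ~1.9 rad knee flexion,
extension to take-off, ballistic flight sized to the requested jump height
(0.40 m default → flight time 2√(2h/g), exact by construction), landing
absorption to ~1.6 rad, recovery.

Construction: knee flexion θ(t) and an ankle-rise (heel-lift) channel a(t)
are prescribed as C² piecewise quintics; poses follow by forward
kinematics with the flexion split 40 % shank / 60 % thigh tilt (keeping
the knee over the foot as in a real squat). The take-off knee state is set
directly to physiologically plausible values (0.5 rad, −4 rad/s) — a fully
knee-driven flat-foot chain would need > 60 rad/s near extension — and the
heel-lift channel supplies the remaining take-off velocity, standing in
for plantarflexion, which the flat-foot model cannot produce. The jump is
bilateral with one instrumented plate under the right foot: on contact the
plate force is exactly half the whole-body inertial force m(a_com + g)
(CoM over right leg + mirrored left leg + pelvis + a head-arms-trunk point
mass), which yields a push-off peak of ≈ 2.7 bodyweights total and an
impulse–momentum closure within 0.1 %. The CoP starts 0.05 m anterior of
the ankle and travels toward the forefoot in proportion to heel lift. A
vertical free moment of −0.004 m × F_y (external torque on the foot) loads
the internal-rotation DOFs so the knee-rotator group actually works;
constant out-of-plane offsets (0.05 rad internal shank rotation, 0.05 rad
thigh adduction) keep the remaining non-sagittal moments nonzero. Four
markers per segment are placed from the packaged clouds, optionally with
Gaussian noise (off by default — the perturbation under study is injected
explicitly); the soft-tissue artifact rotates the shank markers about the
shank long axis by a constant or flexion-coupled angle, reusing the same
noise draws so the artifact is the only change.

Truth bookkeeping: flight-boundary truth frames are the instants the plate
force crosses the 10 N floor (the force tapers smoothly through zero at
the ballistic knots), while the ballistic interval and flight time are
knot-exact; deepest-flexion truth frames come from the spline knots.

What the generator does *not* emulate: foot rotation (the foot stays
flat-oriented; heel lift is translational), arm swing, bilateral asymmetry,
trunk articulation, marker gaps/mislabels, and physiologically validated
inter-joint coordination. Passing tests therefore demonstrate the
*pipeline's* correctness and the *model's* internal sensitivity structure
on motions with the right gross mechanics — they do not validate absolute
load magnitudes against real jumps.

## Phases, summaries, statistics

The airborne interval is the single contiguous run of vertical plate force
below 10 N (configurable); trials with zero or multiple runs are rejected.
Phases 1/2 and 3/4 split at the deepest knee flexion of the pre- and
post-flight contact intervals (first frame of a plateau). Per phase the
peaks of tibiofemoral, patellofemoral and AP shear load
(bodyweight-normalised; shear as the signed extremum of largest magnitude,
anterior negative) and the trapezoidal force–time integral of each rotator
(normalised by bodyweight × airborne duration) are summarised over solved
frames only. Condition comparisons use frames solved in *both* conditions
("corresponding frames"); an own-peak comparison is available behind a
flag. Percent changes with a zero original are reported as NaN, never
infinity.

Across subjects, rotation conditions are compared with a one-way
repeated-measures ANOVA (explicit sum-of-squares decomposition; a
zero-between-condition-variance input returns F = 0, p = 1 rather than
0/0) with Bonferroni-adjusted paired post-hoc tests against the original,
and the bounds condition with paired t-tests, α = 0.05. No sphericity
correction is applied. With two conditions the ANOVA reduces to the paired
t-test (F = t², asserted).

## Problem sizes and determinism

The packaged study conditions are one 561-frame trial per subject at
200 Hz; a full six-condition battery solves ≈ 3,400 force-sharing problems
in ~20 s. The test suite runs one shared battery plus smaller fixtures
(≈ 10 min); the acceptance script runs one battery, a saturated-demand
variant, a six-subject cohort at three conditions, and the numerical
cross-checks. Everything is deterministic given the seed: the pipeline
itself contains no randomness, and all synthetic randomness flows from
`numpy.random.default_rng(seed)`.

## Known limitations

* Absolute joint-load magnitudes (tibiofemoral peaks ≈ 8 BW here) are
  geometry- and task-sensitive; only relative changes across conditions
  are meaningful claims.
* The patellar mechanism and ligament-effectiveness tables are documented
  placeholders.
* Muscle force–length–velocity properties are absent by design: bounds are
  static PCSA × σ_max, as the force-sharing formulation requires.
* The reduced muscle set makes the model's null space smaller than a
  full cadaveric set's; recruitment changes under the bounds condition are
  therefore more pronounced than they would be with 163 elements.
* The hip "joint" truncates the body: everything above it is a point-mass
  HAT in the generator and absent from the dynamic chain, so hip wrenches
  absorb all trunk effects.
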