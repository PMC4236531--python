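# Methods

`capgap` quantifies how much assistive joint moment and power a lower-limb
exoskeleton must supply for activities of daily living (ADL) when the
user's muscles are weakened, and contrasts two sizing philosophies:

* **ID sizing** — size the actuator to the full task requirement, the net
  joint moment from inverse dynamics;
* **AAN sizing** (assistance as needed) — size it to the *capability gap*,
  the part of the task requirement the weakened muscles cannot produce.

## Model and optimization

The musculoskeletal model is a planar sagittal-plane lower limb: hip,
knee and ankle flexion/extension, with extension moments positive at hip
and knee and plantarflexion positive at the ankle, and joint angles
sharing the sign convention of their moments.  The shipped `planar9`
model lumps the major muscle groups into nine Hill-type actuators,
including the bi-articular hamstrings, rectus femoris and gastrocnemius,
which couple the capability of neighbouring joints.

Each muscle produces active force

    F = a · F0 · f_L(l/l_opt) · f_V(v / (l_opt · v_max)),

with `f_L` a Gaussian of width 0.45 around the optimal fiber length and
`f_V` the classic Hill hyperbola for shortening (shape factor 0.25) with
a smooth eccentric rise to a plateau of 1.4; both equal 1 at the
isometric optimum.  The tendon is rigid and passive fiber force is
excluded, so the activated term is the whole muscle moment contribution.
Muscle geometry is reduced to polynomial moment arms r(q) per spanned
DOF; fiber length follows from the exact polynomial antiderivative
(dl = −r dq from the reference posture, where fiber length equals a
configurable reference, by default the optimal length) and fiber
velocity is −Σ r(q_k)·q̇_k.  Because the tendon is rigid, the shipped
optimal fiber lengths are *effective* constants chosen so the normalized
fiber length stays near 1 over ADL joint excursions; they are not
anatomical fascicle lengths.

Muscle weakness is simulated by scaling every muscle's maximal isometric
force by (1 − w), w ∈ [0, 1] in steps of 0.1 by default, which scales
the whole force–length–velocity surface uniformly.

Per time frame, muscle redundancy is resolved by static optimization.
Ideal moment actuators ("reserves") are added at every DOF with a small
optimal moment τ⁰ = 1 Nm, and the frame problem is

    minimize   J = Σ_t a_t² + Σ_m a_m²
    subject to τ_k = Σ_t τ⁰_k a_t + Σ_m gain_{m,k} a_m   for every DOF k,
               0 ≤ a_m ≤ 1,  a_t free,

where `gain_{m,k} = F0·f_L·f_V·r_{m,k}` is the muscle's moment per unit
activation at the frame's posture.  Muscle gains are of order 10²–10³ Nm
while a reserve delivers 1 Nm per unit activation, so reserves are
quadratically costly and the optimum uses muscles wherever it can: at
full strength the reserve share of a DOF's moment is bounded by
τ⁰²·τ/(Σ gains² + τ⁰²), of order 10⁻⁴ Nm/kg on the shipped model.  When
muscles saturate (a_m = 1), the reserve carries the remainder — the
capability gap.  Frames are solved independently (the optimization is
instantaneous; no activation dynamics), with an equality moment
constraint at every DOF.

Numerically, the reserves are eliminated through the equalities,
a_t = (τ_k − Σ gain a_m)/τ⁰_k, leaving a bound-constrained linear least
squares in the muscle activations alone, solved exactly by the BVLS
active-set method (`scipy.optimize.lsq_linear`).  The objective is
strictly convex, so the minimizer is unique and deterministic — no
seeds, no tie-breaking.  The moment constraint holds to round-off by
construction; solutions are certified in tests by a KKT stationarity
residual (multipliers recovered from the reserve stationarity
conditions) and, on tiny instances, by a grid-search oracle.

## Reported quantities

All moments and powers are normalized by body mass (Nm/kg, W/kg).  Per
activity, DOF and weakness level the package reports the gap time
series, its peak per moment direction (extension vs flexion,
plantarflexion vs dorsiflexion reported separately), the gap power
(gap moment × joint angular velocity), and the *weakness tolerance*:
the lowest swept weakness level at which a gap is detected.  Detection
uses a threshold of 0.01 Nm/kg (≈1 Nm for a 100 kg user, configurable)
because the quadratic-cost reserve always leaks a tiny moment, so "a gap
exists" needs a cutoff.  The ID-vs-AAN comparison reports the peak task
moment, the peak gap moment at a chosen weakness level, and the support
fraction — the share of the cycle during which the gap exceeds the
detection threshold (ID assistance is continuous; AAN assistance is
targeted).

Monotonicity in weakness holds for the quantities the analysis reports:
the peak gap per direction and the support fraction are non-decreasing
in the weakness level for every DOF and activity, and the
deficit-direction gap is frame-wise non-decreasing to well below the
detection threshold.  The signed per-frame reserve moment itself is
*not* globally monotone: with equality constraints and bounded
activations, a bi-articular muscle saturated by a neighbouring DOF's
demand can overproduce moment at frames where its other joint's task
moment is small, and the reserve there carries a counter-moment (up to
≈0.1 Nm/kg on the shipped fixtures) that disappears as weakness
approaches 100%.  This is a structural property of the equality-
constrained formulation, worth knowing when reading per-frame gap
curves at low task moments.

## Synthetic trials

No subject data ships with the package; the generator emulates
single-leg sagittal trials of the five ADL.  Joint angles are truncated
Fourier series (cyclic activities: gait 1.1 s, stair ascent 1.4 s, stair
descent 1.3 s) or logistic transitions (sit-to-stand 2.0 s,
stand-to-sit 2.2 s), sampled at 100 Hz, so velocities and accelerations
are available in closed form and cyclic trials close exactly.  Net
moments follow smooth Gaussian-bump profiles over the cycle, scaled to
peak mass-normalized targets per DOF.  The fixture targets follow the
usual ADL demand hierarchy — ankle plantarflexion largest (1.7 Nm/kg in
stair ascent, 1.6 descent, 1.4 gait, ~0.3 chair tasks), knee extension
up to 1.3 Nm/kg in stair tasks, hip extension up to ~0.9 Nm/kg, gait
dorsiflexion smallest at ~0.11 Nm/kg — and the angle phases are set so
plantarflexion moment coincides with plantarflexion velocity in gait and
stair ascent (concentric push-off) but with dorsiflexion velocity in
stair descent (eccentric absorption).  The knee stays slightly flexed
throughout so the leg never straightens into a posture where a point
ground force cannot close the moment balance.

Dynamical consistency is enforced by construction: per frame, a
ground-reaction-style point force on the foot (components and center of
pressure, three unknowns) is solved from the three-DOF moment balance so
that planar recursive Newton–Euler inverse dynamics of the segment chain
(61 kg, 1.72 m anthropometry; standard segment mass/length fractions)
reproduces the target moments; the trial's stored moments are the ID
output itself.  Trial-to-trial variability (`noise_sd`) perturbs the
trajectory coefficients and moment scales multiplicatively with seeded
Gaussian draws, keeping every realization smooth and consistent.

What the generator does *not* emulate: measurement noise on markers or
force plates, double-support load sharing between legs, frontal/
transverse-plane motion, inter-subject anthropometric variation beyond
body mass, or fatigue.  Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under idealized
kinematics and kinetics of realistic magnitude — not that a specific
patient population shows a given tolerance level.

Synthetic EMG: the true activation time series (upsampled to 1000 Hz)
amplitude-modulates a unit-RMS carrier whose instantaneous frequency
wanders across the 20–400 Hz surface-EMG band, plus additive Gaussian
noise scaled by `noise_sd`.  The carrier's rectified low-frequency
amplitude is constant, so the noise-free processed envelope tracks the
activation itself; with a stochastic (noise) carrier the envelope would
fluctuate ~15–20% even without added noise.

## EMG validation

Processing follows standard practice: zero-lag 4th-order Butterworth
band-pass 20–400 Hz, full-wave rectification, zero-lag 4th-order
Butterworth low-pass 10 Hz, normalization to the trial maximum,
resampling to the kinematic frames.  The envelope is compared to the
simulated activation of the unweakened model with a Spearman rank
correlation (average ranks for ties) and a seeded permutation p-value
(999 permutations by default).  Rank correlation is invariant to the
amplitude normalization and to any monotone rescaling of either series.
For muscles recruited through most of the cycle the noise-free chain
yields ρ ≥ 0.95 (filter edge effects prevent exactly 1); muscles with
long zero-activation stretches score lower (ρ ≈ 0.89 for soleus on the
shipped fixtures) because exact ties in the activation meet filter
leakage in the envelope — a property of rank correlation, not a solver
error.  A constant series makes ρ undefined and raises instead of
returning 0.

## Numerical choices and degenerate inputs

* Solver: BVLS with tolerance 1e-12; KKT residuals on certified
  solutions are < 1e-6 (typically < 1e-12).
* Differentiation of sampled series: central differences with one-sided
  ends; optional zero-lag low-pass smoothing (4th-order Butterworth,
  6 Hz typical for 100 Hz mocap) before differencing.  Generated trials
  use closed-form derivatives instead.
* A muscle queried on a DOF it does not span raises (distinct from a
  zero moment arm); non-finite kinematics and non-positive fiber
  lengths raise with the offending muscle named.
* Weakness 1.0 zeroes every gain; the QP then assigns the whole task
  moment to the reserves, so gap ≡ task exactly.
* Reporting resamples trials to 101 points (0–100% cycle); computation
  runs at native sampling.

## Problem sizes

The default analysis — 5 activities × 11 weakness levels × 111–221
frames × 9 muscles — solves ≈ 8,800 QPs in a few seconds on one core.
The grid-search oracle is restricted to ≤ 3 muscles and ≤ 2 DOFs, where
exhaustive enumeration at step 1e-3 is exact enough to bracket the QP
optimum.
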