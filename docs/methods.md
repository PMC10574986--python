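# Methods

## What the simulator is

`kneesim` is a quasi-static rigid-body model of a posterior-stabilized
total-knee-replaced leg on a squat rig. Three rigid bodies (femur with
its femoral component, tibia with baseplate + polyethylene insert,
patella) interact through compliant normal contact and straight-line
soft-tissue elements; the mechanism is driven by a prescribed vertical
hip displacement while a PID controller on the quadriceps tension holds
the vertical ankle reaction at a setpoint. On top of the simulator sit a
ligament-calibration loop and a two-arm sensitivity analysis comparing
the kinematic consequences of (A) collateral-ligament stiffness
perturbations sized to match ultrasound strain-measurement residual
errors and (B) ±3.2° internal–external malrotation of the tibial
components.

Units throughout: mm, N, kg, seconds; degrees at all interfaces (radians
internally). Right-knee convention (X anterior, Y medial, Z proximal);
left knees would be handled by mirroring the geometry into this
convention before simulation.

## Soft tissue

Passive bundles follow the piecewise tensile law with a quadratic toe
region (linear strain limit εl = 0.03) and linear region of stiffness k
(units of force, because strain is dimensionless). The zero-load length
derives from the reference length via L0 = Lr/(εr + 1). Default
parameters per ligament (shared by every bundle of a multi-bundle
ligament, configurable):

| ligament | εr | k (N) |
|---|---|---|
| MCL (2 bundles) | 0.04 | 400 |
| LCL | 0.08 | 650 |
| MPFL | 0.08 | 6000 |
| LPFL | 0.06 | 3000 |
| patellar (3 bundles) | −0.25 | 25000 |

No wrapping, no viscoelasticity: bundles are straight attachment-to-
attachment lines, a known worst-case simplification for sensitivity
studies.

The quadriceps (3 bundles, patella → hip carriage) produces
`Fq = α·exp(β·ΔL) + PID + preload` with α = 85 N, β = 0.05 /mm,
preload 0 N by default. `ΔL` is the tendon elongation relative to its
settled reference length — an absolute-length reading of the exponential
would be astronomically large, so the elongation reading is the only
meaningful one. Hamstrings are 50 N constant-force elements per side.

## Contact

Four analytic primitive pairs: each femoral condyle sphere (r = 22 mm,
centers ±26 mm on the flexion axis) in its spherical insert dish
(r = 30 mm), the cam capsule against the tibial post, and the patellar
sphere (r = 12 mm) on the trochlear cylinder (r = 26 mm). Penetration
depth is the per-pair maximum interpenetration along the normal; the
normal force is `kc δ^2.2` (kc = 5000 N/mm) plus a damping term
(Cc = 10 N·s/mm) that is identically zero along the quasi-static path
(optionally ramped over the first 0.01 mm of penetration to avoid a
touchdown discontinuity in any dynamic use). No friction — the law is
purely normal. An 8 mm dish/condyle radial clearance gives the joint a
pendulum-like secondary compliance so that ligament-tension changes can
actually move the equilibrium; a fully conforming joint would bury every
soft-tissue effect under the penetration stiffness.

## Settling and reference lengths

The reference length of every bundle is defined at a settled
full-extension pose: the tibia is held at its generated orientation, the
patella at its generated seat, and the femur (hip height + sagittal
angle) equilibrates under gravity and contact so the condyles seat in
the dishes. Because referencing changes the ligament loads, the
settle/re-measure pair is iterated to a fixed point (|ΔLr| < 1e-11 mm),
which makes settling idempotent to well below 1e-9 mm. Bundles attached
to the externally held patella transmit no force during this step. The
quadriceps reference length (zero elongation) is fixed at the same pose.

## The squat cycle

The hip-height profile is derived from the flexion trajectory
35° → 90° → 35° (raised-cosine over the cycle) by two-link closure;
101 samples and a 0.1 s control step by default. Per sample:

1. the hip PD (velocity form, gain clamped to deadbeat) updates the
   simulated hip height;
2. the quadriceps PID (kp = 2, ki = 18, kd = 0; output clamped at
   ±5000 N; integral anti-windup) updates the tendon force from the
   previous sample's measured ankle load;
3. the 11 unconstrained pose coordinates (femur sagittal angle, tibia
   3 rotations + medio-lateral shift, full patellar pose) are driven to
   static equilibrium.

The gains were fixed once by loop-shaping against the measured
quad-to-ankle-load gain of the default model (≈0.25 N/N near the
setpoint) and stored as protocol defaults; the controller reaches the
90 N setpoint within the first half cycle and holds the second-half mean
within 1%. The control step is part of the loop design: protocols that
need fewer samples should shorten the cycle, not stretch the timestep.

The ankle constraint deserves a note: the physical rig leaves five ankle
degrees of freedom and eliminates anterior–posterior displacement. A
quasi-static model additionally needs a vertical support for the 90 N
load to react against, so the ankle point is fixed vertically as well
(the reported ankle load is that constraint reaction) with
medio-lateral translation and all rotations free.

### Solver

All elements are conservative (constant-tension actuators included), so
static equilibrium is both a root of the generalized-force residual and
a minimum of an exact potential. The solver exploits both views:

* damped Levenberg–Marquardt Newton on the residual (finite-difference
  Jacobian, reused across iterations and warm-started samples, refreshed
  on rejection), per-coordinate step caps;
* for cold starts and flat valleys — typically a slack bundle about to
  engage, where the Hessian collapses — a block Gauss–Seidel sweep
  (patella subsystem, then the bone linkage) followed by box-bounded
  L-BFGS-B descent on the exact potential energy, recentered on the
  exponential map.

Convergence tolerance is 1e-5 N (scaled; torques at a 100 mm arm) for
squat samples and 1e-8 N for settling; at joint stiffnesses of order
10–1000 N/mm these map to pose noise far below the strain-difference
resolution the sensitivity analysis needs. Samples warm-start from a
replay of the previous solved motion increment scaled to the hip step,
which captures the contact-compliant path to first order. The solution
is deterministic: identical model + protocol give bit-identical traces.

A rare fallback accepts a sample at a residual below 1e-2 N with a
logged warning; this occurs only at extreme perturbation stiffnesses and
is mechanically negligible (≲1e-3 mm of pose error).

## Calibration

The multi-criteria goal (minimize kinematic/load RMSE, maximize Pearson
correlation) is scalarized as Σ w_c [RMSE_c/range_c + (1 − ρ_c)/2] over
the six joint DOFs plus ankle and quadriceps loads (weights default
to 1; the scalarization is a declared convention — the original tuning
was manual and states no trade-off rule). The search is cyclic
coordinate descent with golden-section line search (log-spaced for
stiffnesses), accepting only improvements, so the objective history is
non-increasing; no global optimality is claimed. On noise-free
self-generated references the default model recovers a single detuned
stiffness within 10%.

## Sensitivity analysis

The strain-difference statistic used for matching is the cycle maximum
of the absolute bundle-averaged strain difference (a declared choice —
the conservative summary giving the narrowest stiffness window; mean and
at-peak-flexion summaries are selectable). Reference strains are held
fixed and the nominal settle is reused, so only k varies. The search
expands geometrically from the nominal stiffness until the target is
bracketed, then bisects until the achieved difference is within 1.5% of
the target; an inactive ligament (no force anywhere in the cycle)
returns the "/" sentinel, and an unreachable target is returned at the
bound with a flag, never silently. The implant arm rotates baseplate +
insert about the tibial long axis through the baseplate center (the
rotation center is not prescribed anywhere authoritative) with ligament
parameters and reference lengths unchanged.

## What the synthetic knee does and does not show

The generator stands in for CT-derived, specimen-specific geometry with
analytic primitives and atlas-style attachment sites scaled to the
segment dimensions (femur 320 mm, tibia 280 mm shafts). Its geometry
was designed so the mechanism behaves like the instrumented cadaveric
knees it emulates: the quadriceps modulates the ankle load with positive
gain across the cycle, MCL strain rises toward the linear region with
flexion, and LCL strain falls toward slack in deep flexion. Passing
tests therefore demonstrate the *protocol* — settling, regulation,
calibration, perturbation matching, and the qualitative sensitivity
ordering (internal–external rotation most affected; implant malrotation
outweighing ultrasound strain error) — not specimen-specific numbers.
In particular the conforming spherical joint couples collateral strain
to pose more stiffly than a real post-TKA knee with several degrees of
laxity, so the strain-matched stiffness windows are far wider than a
cadaveric model would give, and the MCL decreased-stiffness direction
saturates below the 0.27% target (reported as a bound hit). Real-data
features not emulated: irregular articular geometry, wrapping and
capsule structures, measurement noise, specimen-to-specimen variability
(beyond optional seeded attachment jitter).

## Numerical and degenerate-input choices

* Rotation matrices are re-orthonormalized (SVD projection) after every
  incremental update; poses validate orthonormality at 1e-9.
* The joint decomposition raises an explicit singularity error when the
  tibial long axis is parallel to the femoral flexion axis (VV → ±90°).
* Correlation of a constant channel is undefined; calibration scores it
  at the worst case (identical constant channels score perfectly).
* Negative correlations fall in the "weak" band — the bands partition
  only by upper bounds.
* Empty kinematic series, mismatched grids, non-watertight parameters,
  and out-of-range implant rotations (|angle| > 15°) raise typed errors
  naming the offending input.

## Known limitations

* Quasi-static only: no inertial effects, no contact damping on the
  solution path; the cycle timestamp is a control step, not physical
  dynamics.
* Single implant family (posterior-stabilized primitives); no
  cruciate-retaining variant, no other implant perturbation DOFs.
* The stiffness-window magnitudes are properties of the synthetic
  geometry and transfer to real knees only qualitatively.
* Bit-exact trace invariance under perturbation of a never-taut ligament
  holds for the mechanical content (zero force, equilibria equal) but
  not for the solver's floating-point path, whose trial steps may
  transiently tension the slack bundle; traces agree to ~1e-6.
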