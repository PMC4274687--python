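# Methods

## Overview

`annulustrack` measures the aortic annulus diameter in a 3D echocardiographic
volume sequence by tracking a deformable model of the left ventricular
outflow tract (LVOT) and aortic root with an extended Kalman filter (EKF).
The model is a cylindrical Doo-Sabin subdivision surface — 5 rings of 6
control points — whose state consists of a 7-parameter global similarity
transform x_g = [t_x, t_y, t_z, s, θ_x, θ_y, θ_z] and 30 local radial
displacements x_l (one per control point, each along its fixed outward
direction perpendicular to the long axis).  A rigid disc at the model's
mid-height represents the annulus plane; it shares the global transform and
is not deformable.

Per frame the filter (i) predicts the state from a motion model,
(ii) probes the image along surface normals at ~300 tube samples and 40
disc-rim samples, fitting a step or peak template to each 1D intensity
profile by least squares, and (iii) assimilates the resulting scalar edge
displacements in information form:

    x_pred = A x_prev + (I − A) x_0,k        P_pred = A P_prev Aᵀ + Q_0,k
    P_post⁻¹ = P_pred⁻¹ + Σᵢ hᵢ rᵢ⁻¹ hᵢᵀ     x_post = x_pred + P_post Σᵢ hᵢ rᵢ⁻¹ vᵢ

with hᵢ = Jᵢᵀ nᵢ the measurement vector of edge i (surface Jacobian
projected on the probing direction).  The update cost is one state-sized
solve regardless of the number of edges.

Tracking runs in two phases.  The **stiff** phase removes the deformation
states and estimates the 7 global states only, sweeping the cycle twice
(warm-up, then recorded) with a constant rest state (the initial pose) and
constant process noise.  The **deformable** phase reintroduces the 30 radial
states, uses the per-frame stiff pose and covariance as the motion model's
rest state x_0,k and process noise Q_0,k, tracks the cycle forward and
backward, and fuses the passes per frame by precision weighting
P = (P_f⁻¹ + P_b⁻¹)⁻¹.  The annulus contour is the intersection of the
deformed surface with the disc plane; a conic-constrained least-squares
ellipse fit (with Sampson-distance refinement) yields major/minor diameters,
area, perimeter (complete elliptic integral), and the equal-area and
equal-perimeter circle diameters.  Mid-systole is the frame of maximum
fitted annulus area, and the perimeter-derived diameter at mid-systole is
the headline output (it varies least over the cycle, so it is insensitive
to mid-systole detection error).

## Geometry details

**Subdivision.**  Doo-Sabin refinement uses the standard weights
α₀ = (n+5)/4n, αⱼ = (3 + 2cos(2πj/n))/4n per face of valence n.  Because
the scheme is linear with fixed topology, the map from control points to
refined vertices is precomputed once per topology as a weight matrix; three
refinement levels (≈1250 vertices) put the mesh within ~0.01 mm of the
limit surface for these mesh sizes.  The open cylinder ends use the same
weights on the truncated neighborhood (edge- and vertex-faces are simply
not built across the boundary).  A control ring circumscribes its limit
curve: for hexagonal rings the limit radius is ≈0.872 of the control
radius (`limit_shrink_factor`), and the pipeline divides the requested
initial diameter by this factor so the *rendered surface* matches D₀.

**Sampling and Jacobians.**  300 tube samples sit on a fixed 20 (angular) ×
15 (axial) parameter grid of the reference surface — the same refined
vertices are tracked regardless of the deformation state.  Column j of a
sample's deformation Jacobian is its subdivision weight for control point j
times that point's radial direction; this is exact (the scheme is linear)
and is verified against central differences.  Normals are area-weighted
vertex normals oriented radially outward (the tube is star-shaped about its
axis).

**Disc probing.**  On a stiff cylinder every radial normal has zero axial
component, so the axial position t_z would be unobservable from tube
samples alone.  The 40 disc-rim samples therefore probe *along the disc
normal* during the stiff phase, fitting a peak template only: at the rim
radius, the wall intensity along the axis peaks at the echogenic annulus
band, which anchors the annulus plane's axial position and tilt.  In the
deformable phase — once the surface carries the waist/bulge shape whose
tilted normals provide axial information — the disc probes radially,
reinforcing the waist radius at the measurement plane.

## Filter tuning

All values live in `PhaseConfig`/`EdgeConfig` and the YAML run config.

| parameter | stiff | deformable | rationale |
|---|---|---|---|
| A diagonal, translation/scale/rotation | 0.9 / 0.95 / 0.9 | 0.98 | stiff: mild smoothing toward the initial pose; deformable: the pose is trusted from the stiff phase and held nearly constant — apparent motion is absorbed by the deformation states, and the annulus plane stays aligned with the LVOT axis |
| A diagonal, deformation | — | 0.7 | regularizes toward the undeformed shape |
| Q₀ SDs (t, s, θ) | 2 mm, 0.05, 3° | per-frame P_stiff,k | stiff: order of magnitude from the capture range |
| q_def (deformation process noise SD) | — | 1 mm | permits per-frame shape change |
| P₀ SDs | 10 mm, 0.2, 0.2 rad | deformations 4 mm | weak prior; capture handled by the edge search |
| search length / samples | ±14 mm / 29 | ±7 mm / 21 | ±14 mm capture for initialization errors; finer, shorter profiles after alignment |
| r_edge | 80 mm² | 80 mm² | total edge variance; over ~340 edges this is a per-edge σ of ≈0.5 mm, the realistic accuracy of a profile edge fit.  Much smaller totals make every edge overconfident and let the filter amplify systematic model-vs-anatomy residuals along ill-conditioned deformation directions |
| min step height | 10 % of the robust (1–99 %) intensity range | same | rejects speckle-only fits |
| neighbor max Δv | 3 mm | 3 mm | one order-independent sweep against the median of grid-adjacent accepted neighbors |

Three engineering choices beyond the core recipe, each motivated by an
observed failure mode and documented here as the package's own design:

1. **Scale renormalization between phases.**  The scale state multiplies
   radius and length alike, so a wrong D₀ would leave the converged model
   with stretched or compressed ring spacing and a D₀-dependent axial
   smoothing of the radius profile.  After the stiff phase the control net
   is rebuilt at the median fitted scale and the per-frame scales divided
   out; the deformable-phase geometry is then independent of the initial
   guess (the D₀-sweep SD drops an order of magnitude).
2. **Median pass initialization.**  Both deformable passes start from the
   component-wise median stiff pose (and median covariance).  A single
   frame's stiff pose can be caught on a secondary attractor of the axial
   edge search; since the deformable pose is heavily regularized
   (A = 0.98), the pass-initial value dominates and must be robust.
3. **Per-pass warm start.**  Each deformable pass iterates its first frame
   twice before the recorded sweep (the stiff phase's warm-up sweep,
   confined to one frame); otherwise the pass-end frames carry an
   undeformed-model transient that can win the max-area mid-systole vote on
   non-pulsating recordings.

Numerical hygiene: covariances are re-symmetrized with an eigenvalue floor
of 1e-10 after every predict/update; the information system is solved by
Cholesky factorization with a ridge fallback; variance normalization guards
zero residuals with ε = 1e-6·max(residual, 1).  Template fits refine the
discrete minimizer by parabolic interpolation of the residual curve
(clipped to half a sample step, suppressed for exact fits).  Ellipse
fitting uses the direct conic-constrained algebraic fit followed by
Levenberg–Marquardt on Sampson distances; degenerate inputs (fewer than 5
points, collinear sets, non-elliptical conics) raise a per-frame
measurement failure that is recorded, not fatal.  The whole pipeline is
deterministic; randomness exists only in the phantom generator and the
sensitivity protocols, both seeded.

## The synthetic phantom

The phantom renders a bright tubular wall (Gaussian cross-section, σ =
half the 3 mm wall thickness) around a surface of revolution whose radius
profile R(z) is a monotone cubic through: ventricular flare 16 mm →
LVOT 11 mm → annulus waist 12 mm (z = 0) → sinus of Valsalva 16 mm
(z = 8 mm) → ascending aorta 13 mm, over a ±24 mm tube in a 96³ grid at
0.7 mm isotropic spacing, 10 frames per cycle.  Each frame applies a rigid
pose (3 mm translation, 5° rotation amplitudes over the cycle), a radial
pulsation (+5 % Gaussian bump peaking at frame 3), multiplicative Rayleigh
speckle smoothed to a ~1.5-voxel correlation length, and optionally a
signal-dropout cone or an additive stitching seam.  The wall brightens 3×
in an axially thin (σ = 1.5 mm) band at the annulus, emulating the
echogenic fibrous/calcific annulus typical of the TAVI population; this
band is what the stiff phase's axial disc probes detect.  Ground truth
(per-frame annulus center, plane normal, diameter 2·R_a·pulse, area,
perimeter, rigid pose) is exact by construction.

What the phantom does *not* emulate: point-spread function and attenuation
physics, scan conversion, valve leaflets, chamber structures other than the
outflow tract, and real anatomical variability.  Passing tests therefore
demonstrate the estimator's geometric and statistical correctness and its
robustness to initialization, speckle, dropouts and stitching — not
clinical accuracy, which in the source study was established on patient
recordings that are not distributable.

Known limitations observed on the phantom suite: the 5-ring model smooths
the waist valley (quadratic B-spline behavior across 10 mm ring spacing),
leaving a systematic overestimate of ~0.5 mm on the default geometry —
within the 3 % acceptance band but visible; and a very wide sinus directly
above a narrow annulus (the `wide-sinus` case) captures the measurement
plane and grossly overestimates the diameter, the same failure mode the
source method reports on its worst patient case.

## Problem sizes used in validation

Unit and property tests run on small meshes and volumes (48–96³).
End-to-end recovery uses the default 96³ × 10-frame phantom.  The
sensitivity protocols run 50 repetitions per perturbation magnitude
(translation d = 2,4,…,12 mm; rotation φ ∈ {1, 5, 10, 15}°) and 25
linearly spaced initial diameters in [15, 35] mm; one full segmentation
takes ~0.3 s, a full sensitivity battery ~2 minutes on one CPU.
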