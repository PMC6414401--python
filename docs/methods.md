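# Methods

## Shape model

Surfaces are triangle meshes in millimetre world coordinates. A mesh `S`
is represented as a *varifold*: a sum over triangles of Diracs carrying
the triangle centre `c_k` and the area-weighted normal `τ_k` (norm equal
to the triangle area). Two surfaces are compared through the kernel inner
product

    <[A],[B]> = Σ_kl exp(−|c_k − c_l|²/λ_w²) (τ_k·τ_l)² / (|τ_k||τ_l|),

a Gaussian spatial kernel times a squared-cosine directional kernel. The
squared cosine makes the metric blind to triangle orientation, so winding
conventions never matter, and no point correspondence between meshes is
needed. The squared distance follows by polarisation. The directional
kernel is the standard construction for non-oriented surface comparison;
the printed functional form of the representation does not pin it down
uniquely, and we adopt the construction used by the established
shape-analysis software in this area. Both the varifold kernel and the
deformation kernel use the convention `exp(−|Δ|²/λ²)` with no factor 2.

Deformations are flows of velocity fields spanned by a Gaussian kernel
`K_V` of width `λ_v` over `n` control points: `v(y) = Σ_p K(y, x_p) a_p`.
Geodesics in the induced metric satisfy the canonical equations of the
Hamiltonian `H = ½ Σ_pq (a_p·a_q) K(x_p, x_q)`:

    dx_p/dt = Σ_q K(x_p,x_q) a_q,
    da_p/dt = −Σ_q (a_p·a_q) ∇₁K(x_p,x_q).

These equations are not printed in the usual presentations of the
discrete parametrisation; they are the standard canonical system for the
kinetic-energy Hamiltonian and are documented here and next to the code.
`H` is conserved along exact geodesics, which is the central correctness
check on the integrator.

## Numerics

* **Integration.** Fixed-step RK4 on `[0,1]`; 11 steps by default.
  Measured energy drift at 11 steps is ~1e−9 relative on
  moderate-curvature systems and shrinks ~16× when the step halves
  (4th-order behaviour). Mesh vertices are integrated jointly with the
  control-point system so the time-varying field is sampled consistently
  at every Runge–Kutta stage.
* **Gradients.** All matching energies are minimised with exact
  reverse-mode derivatives written by hand through the discrete RK4
  recursion (`diffeo.rk4_backprop`); they agree with central finite
  differences to ~1e−9 relative, far inside the 1e−3 contract. No
  autodiff framework is used.
* **Optimisation.** L-BFGS-B (scipy) with its line search; the objective
  history across accepted iterates is recorded and non-increasing.
  `gtol` is scaled by the initial objective so convergence behaviour is
  insensitive to the (unnormalised) varifold energy scale.
* **Degenerate inputs.** Triangles below a 1e−12 mm² area floor are
  dropped at validation; a mesh with no surviving triangle is rejected.
  Zero momentum vectors get cosine 0 in the cluster similarity; zero mean
  vectors get axis angles (π/2, π/2, π/2).

## Pipeline stages and their assumptions

* **Mirroring.** The analysis is made blind to hemisphere by reflecting
  the right structure across the cohort mid-sagittal plane, estimated as
  the mean x-coordinate over all meshes (configurable). Winding is not
  re-flipped after mirroring — the varifold metric does not see it.
* **Bilateral mean.** One deformation `χ` is applied to both sides and
  pulled toward a common mid-shape `S`, alternating an `S`-update (vertex
  average of the two flowed sides) with re-estimation of `χ`; the
  alternation starts with the `S`-update at zero momenta, which makes the
  scheme exchangeable in its inputs and avoids a fixed point where `S`
  collapses onto the initialisation. The vertex-average update assumes
  the two sides share vertex count and ordering, which holds for
  mirrored copies of a common template (as in the synthetic cohort); for
  meshes without correspondence a varifold-barycentre update would be
  needed instead.
* **Baseline.** Diffeomorphic iterative centroid over the `k = 10`
  subjects furthest from onset (most negative EYO; ties broken by subject
  id): one sequential pass in a seeded random order,
  `C_{j+1} = C_j` flowed `1/(j+1)` of the way to the next shape (momenta
  scaled by `1/(j+1)`, which equals flowing partial time along the
  geodesic). The result depends mildly on the ordering; the seed is
  recorded in provenance.
* **Regression.** EYO is affinely mapped to internal time `[0,1]`; the
  geodesic is integrated with `T−1` RK4 steps so the integrator knots and
  the `T = 30` snapshot grid coincide, and each subject's varifold data
  term attaches to the nearest grid knot (the printed discretisation).
  Snapping contributes a per-subject error of up to half a grid interval
  (~1 EYO year) times the local trajectory speed.
* **Residuals.** The snapshot nearest the subject's EYO is registered to
  the subject's mean shape, with control points at the snapshot's own
  flowed grid positions; γ and both kernels are inherited from the
  trajectory configuration.
* **Transport.** Momenta are carried one grid interval at a time along
  the time-reversed geodesic using central differences of perturbed
  exponentials; stepping interval-by-interval keeps the finite-ε error
  uniform across subjects sitting at different distances from baseline,
  instead of letting it accumulate differently per subject. The
  difference of exponentials measures a transported *velocity*; momenta
  are converted to velocities with the kernel matrix before the step and
  back (a regularised symmetric solve) after it. This realisation makes
  transport exactly the identity on a flat trajectory, linear to ~1e−3,
  second-order in ε (Richardson-verified), and V-norm-preserving within
  2% on curved trajectories — parallel transport is an isometry, and the
  residual error is finite-ε plus grid discretisation. ε defaults to
  1e−3 times the trajectory-to-residual momentum norm ratio.
* **Clustering.** Similarity weights (5, 2, 1) follow the published
  formula. With raw millimetre distances the −5‖Δx‖² term dwarfs the
  angular and magnitude terms on an 11 mm grid, so by default the
  distance is divided by `λ_v` before squaring (raw mode available).
  Similarities become affinities via `exp(s/τ)` with `τ` the
  interquartile range of `s` — a scale-free choice; planted-partition
  recovery is insensitive to `τ` within a factor ~4. The normalised
  Laplacian embedding (scikit-learn) is discretised with the rotation
  (Yu–Shi) scheme re-started `n_init` times from seeded random
  orthogonal matrices; the labelling with the lowest within-cluster
  inertia in embedding space wins. `n_init` defaults to 3000 as
  published; the test profile uses 50.
* **Descriptors.** Orientation PCA is fit per cluster across subjects
  (the axis-angle matrix is centred and projected on its first principal
  axis, sign fixed so the largest-magnitude component is positive).
  Whether that PCA is per-cluster or global is not fully determined by
  the published description; per-cluster is our reading.
* **Statistics.** REML linear mixed model per cluster × descriptor with
  a family random intercept; Wald χ² tests (T1 joint carrier +
  carrier×EYO with df 2 — identified as the joint test by the published
  degrees of freedom — and T2 interaction-only with df 1), Bonferroni
  over the 2K overall tests; grid contrasts `b1 + b3·t` every 5 years
  from −20 to +10, Bonferroni over the 7 grid points, confidence
  intervals at the corrected level. Age is not a covariate (it is nearly
  collinear with EYO). If the mixed fit fails (singular random-effects
  covariance, one family), the model falls back to OLS with a warning;
  the L-BFGS fit is retried with other optimisers first. Measured
  type-I error of T1/T2 at n=200, 60 families is ~0.05–0.06 against the
  asymptotic χ² reference.

## Synthetic cohort: what it emulates and what it does not

The generator stands in for a familial-dementia imaging cohort: ~200
subjects (carrier fraction 113/211), EYO uniform on [−40, 20] years, 60
families, 5 sites, bilateral thalamus-scale ellipsoids (semi-axes
11×7×6 mm, icosphere meshes; subdivision 3 ≈ 642 vertices by default,
4 ≈ 2562 for structure-scale realism) at ±15 mm from the mid-sagittal
plane. All subjects share one ground-truth geodesic (an anterior-pole
compression of ~3 mm over the span — the scale of reported presymptomatic
subcortical change) plus a common residual deformation of 1 mm amplitude
concentrated on an anterior-dorsal patch, i.i.d. vertex jitter of 0.15 mm
(segmentation-noise scale), and independent left/right jitter after
mirroring.

The planted group effect rotates the carriers' residual direction after a
divergence onset at EYO −10, with exponential kinetics
`angle(t) = A·expm1(k·(t−onset))/expm1(k·30)`, `k = 0.2`/yr, `A = 45°` at
the top of the range, under a 6° per-subject orientation wobble, at
strictly constant amplitude — so group means differ in direction only.
These defaults were fixed by an a-priori design analysis: with the linear
carrier×EYO mixed model, a divergence that grows *linearly* after onset
produces significant extrapolated contrasts two or three grid points
before the true onset at any detectable effect size (the fitted contrast
line crosses zero near EYO −25), so onset localisation is only possible
for accelerating kinetics; exponential acceleration is also the standard
kinetic model for presymptomatic neurodegenerative change. In amplitude
mode the same ramp multiplies the residual amplitude instead (in percent),
with direction fixed.

What the generator does **not** emulate: real thalamic anatomy and its
segmentation bias fields, site- or scanner-specific geometry effects
(site enters only as a model covariate), family-correlated shape effects
(the family random intercept is exercised by the statistical simulations,
not by the mesh generator), longitudinal within-subject correlation, and
non-uniform EYO sampling. Passing tests therefore demonstrate the
estimator chain is correct and calibrated under known ground truth, not
that effects of this size are detectable in any particular real cohort.

The repeated onset-detection experiment (200 cohorts) operates at the
descriptor level: it draws the same covariates and residual-direction
model as the mesh generator and forms the planted cluster's mean vector
directly (with a 10% coefficient-of-variation amplitude measurement
noise), skipping mesh synthesis and registration, whose fidelity the
inverse-crime benchmarks certify separately. A full-mesh run of all 200
cohorts would cost hours per repetition set with no additional inferential
content at that level.

An important caveat established during validation (and visible in the
acceptance output): a single full-geometry pass at these study conditions
localises the planted support region by clustering, but the per-subject
orientation signal reaching the descriptors is attenuated well below the
momentum-level signal-to-noise: with 1 mm residuals the cluster-mean
direction noise after regression, registration and transport is several
times the planted orientation wobble, dominated by grid-time snapping,
absorption of the cohort-mean residual into the single trajectory, and
regularisation shrinkage (it persists with vertex jitter switched off, so
it is a discretisation property of the estimator chain, not measurement
noise). Corrected group significance in one 200-subject full-geometry run
is therefore not expected at these conditions.

## Problem sizes used in the shipped checks

Benchmarks run on one CPU: icosphere subdivision 1–2 meshes (42–162
vertices), 11 mm deformation and 5 mm varifold kernels, grids of 48–80
control points, registration budgets of 30–150 L-BFGS iterations, 1000
null simulations for calibration, 200 descriptor-level cohorts for onset
detection, and one full 200-subject pipeline at subdivision 2 with the
test profile (`n_init` 50, 5 RK4 steps, 1 bilateral round).
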