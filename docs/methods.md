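# Methods

## Problem

During diastole the left ventricle (LV) fills under a rising cavity
pressure while the myocardium finishes relaxing. In diseased hearts
relaxation is impaired and a residual active tension (AT) persists into
filling, so the observed motion confounds two very different quantities:
the passive stiffness of the tissue and the decaying contractile stress.
`diastolefit` jointly estimates, from a series of diastolic shapes with
synchronous cavity pressures:

* the passive constitutive parameters of a Fung-type transversely
  isotropic (Guccione) law,
* the unloaded (zero-pressure, zero-tension) reference configuration, and
* the residual AT value at every diastolic frame.

## Constitutive model

The strain-energy density is

    W = c1 (exp(Q) - 1),
    Q = c2 Eff^2 + c3 (Ess^2 + Enn^2 + 2 Esn^2) + c4 (2 Efs^2 + 2 Efn^2),

with E the Green–Lagrange strain in the local fiber/sheet/sheet-normal
frame, `c1` in kPa and `c2..c4` dimensionless. Because the four parameters
are strongly coupled in inverse problems, estimation uses the reformulated
set `(c1, alpha, r2, r3, r4)` with `alpha = c2+c3+c4` (stiffness scale of
the exponent) and the anisotropy fractions `r_i = c_i/alpha` summing to 1.
The total second Piola–Kirchhoff stress adds a hydrostatic term `p C^-1`
(incompressibility) and a length-dependent active fiber stress

    Ta = t_z (1 + beta (sqrt(2 Eff + 1) - 1)),

where `t_z` (kPa) is the combined reference tension times activation level
— the two are never separated — and `beta` (default 1.45, configurable)
is the linear length-dependence coefficient in the convention of the
Hunter–McCulloch–ter Keurs family of active-tension models. No value of
`beta` is canonical for residual diastolic tension; the default is shared
between the data generator and the estimator, so no result in this package
depends on its exact value.

## Reduced-order forward model

Clinical-scale implementations of this workflow drive a full
cubic-Hermite finite-element LV; this package replaces that with a
desk-scale reduced model that preserves the
operator contract the estimator needs — a forward inflation operator
`x_i = M(x0, C, P_i, Tz_i, bc)` and a backward deflation operator
`x0 = M^-1(x_i, C, P_i, Tz_i, bc)` that are mutual inverses — while
keeping all four constitutive parameters mechanically load-bearing.

Geometry: an axisymmetric truncated thick-walled ellipsoid. Shells at
transmural coordinate `lam in [0,1]` have semi-axes
`a(lam) = a_endo + lam h` and `c(lam) = c_endo + lam h`; the wall is cut by
a base plane at `z = f c_endo` (truncation fraction `f`) and closed at the
apex. The fiber helix angle varies linearly across the wall (+60° endo to
−60° epi by default), the sheet direction is transmural, and the
sheet-normal completes the triad. Defaults (endocardial radius 20 mm, wall
thickness 10 mm, base-to-apex length 60 mm, `f = 0.5`) give an unloaded
cavity of ~57 ml and a wall of ~91 ml — a physiologic human LV.

Kinematics: deformed configurations live in an eight-dimensional
Rayleigh–Ritz family combining slice-wise radial motion and slice-wise
rigid rotation (torsion) at fixed axial coordinate:

    rho'^2 = rho^2 + sum_m q_m G_m(z),     G_m = zbar^j eps^p,
    theta' = theta + sum_m t_m Psi_m(z),   Psi_m = ((z_b - z)/c_endo)^m,
    z'     = z,

with `eps = max(0, 1 - (z/c_endo)^2)`, `(j, p)` ranging over
`{0,1} x {3/2, 5/2, 7/2}` and `m in {1, 2}`. Three properties are exact by
construction: det F = 1 pointwise (each slice map is area preserving), the
base plane and apex are fixed (emulating prescribed kinematic boundary
data), and the deformation gradient stays bounded at the apex (every
radial basis decays at least like `eps^(3/2)`; a plain elliptical profile
would produce a shear singularity there). Exact incompressibility means
the hydrostatic multiplier does no work under variations of the DOFs and
drops out of equilibrium.

Equilibrium is the Galerkin projection of virtual work onto the family:
eight equations `sum_g w_g (S_passive + Ta f⊗f) : dE/dq_m = P dV/dq_m`,
with the cavity volume exactly linear in the radial DOFs and twist
neutral. They are solved by damped Newton (forward-difference Jacobian,
backtracking line search) under load stepping (≤ 0.25 kPa pressure,
≤ 1 kPa tension per step) with warm starts; the returned state satisfies
the balance to a relative tolerance of 1e-8. Everything is deterministic.

The dimensionality of the family is a deliberate choice: with a single
inflation DOF the frame objective collapses to one scalar and the
anisotropy fractions are unidentifiable from a single frame; eight
observation DOFs overdetermine the three free constitutive parameters, and
the torsional mode couples directly to the helical fiber field.

Quadrature: tensor-product Gauss–Legendre with 5 points transmurally and
longitudinally and 8 equally spaced circumferential stations (the optimal
rule on the circle), weights normalized to the exact wall volume. The
radial basis has square-root endpoint behaviour at the apex; at order 5
doubling the order moves the loaded cavity volume by well under 0.1%,
which order 4 narrowly misses. The count is configurable.

Point-cloud references: because the ansatz keeps the axial coordinate
material, any configuration reachable by the model can itself serve as the
unloaded reference (its radii and twist angles replace the parametric
family shape; triads and weights come from the best-fitting family
member). The estimation pipeline uses this to take "the reference state is
observed frame k" literally, and deflation is a damped fixed point on the
reference cloud (update = observation − inflate(current), damping 0.8, cap
100 iterations): on convergence the inflated reference reproduces the
observation point by point. The public `deflate` returns the best-fitting
member of the parametric family, plus the converged cloud on request.

## Mesh fitting

The mesh-propagation stage of the clinical workflow is implemented
standalone: tensor-product cubic-Hermite meshes (value + derivative DOFs
per node, C1-continuous across shared faces by construction) are fitted to
tracked material-point displacements by the linear least-squares solve
`U_i = (H^T H)^-1 H^T (H U_j + z)`, per field component. Derivative DOFs
are taken with respect to the unit local coordinate (no arc-length
scaling), which keeps the solve free of per-element scale bookkeeping; no weighting
scheme is canonical for this fit, so the default is unweighted with an optional per-point diagonal weight vector,
and an optional Tikhonov term (default 0, logged when nonzero) covers
rank-deficient layouts.

## Estimation pipeline

The inverse problem is under-determined (n frame objectives, n + 2
unknowns) and is closed by two assumptions: the myocardium is fully
relaxed at end-diastole (`Tz(n) = 0` exactly), and the unloaded state is
initially approximated by one of the observed frames (`x0 ~ y_k`, the
frame where inflating pressure and contracting tension roughly balance).
For each candidate reference frame k (processed lazily in increasing k):

1. the reference is set to the observed frame-k point cloud;
2. the constitutive parameters are estimated from the end-diastolic frame
   by grid sweeps in the reformulated parameterization. `c1` is held fixed
   (default 1 kPa) because of the c1–alpha coupling; `alpha` is swept on a
   32-point log grid over [1, 400] with the anisotropy fractions fixed,
   then `(r3, r4)` on the 0.05-step simplex grid with `alpha` fixed,
   alternating until the winning cell stops changing (cap 10). Because
   coordinate descent can stall on the diagonal valley of this objective
   while the minimization is defined as the global minimum across the
   grid, a band sweep then evaluates the full (r3, r4) simplex for every
   alpha within ±3 cells of the incumbent, iterating until stable, and
   the returned point is the minimum over every cell evaluated. Ties
   prefer smaller `alpha`, then smaller `r3`, `r4`.
3. the reference is refined by deflation from the end-diastolic
   observation (so the fitted model reproduces end-diastole exactly);
4. `Tz(i)` is estimated per earlier frame by a 1-D sweep of the frame
   objective over [−10, 30] kPa at 1 kPa, refined around the coarse
   optimum at 0.033 kPa (ties prefer smaller |Tz|; range-boundary optima
   are flagged);
5. the tension criterion accepts the smallest k whose profile is
   monotonically decreasing and ends positive. Monotonicity carries a
   tolerance equal to the refinement step (0.033 kPa) so grid quantization
   cannot flip it; positivity is the strict physiological inequality
   `Tz(n−1) > 0`. A profile that is identically ~0 fails strict positivity
   but is the physiologic healthy limit, so if no candidate passes and the
   k = 1 profile is all-zero within tolerance, k = 1 is accepted with a
   "no residual AT detected" flag.

The frame objective is the unweighted mean squared Euclidean distance over
the (optionally masked) material points, reported together with its square
root. The free-wall mask exists to exclude regions whose motion is
dominated by structures outside the model (in the clinical setting, the
septum facing the right ventricle); the reduced axisymmetric anatomy has
no such region, so the synthetic cases compare all points by default.

Identifiability tooling: `analyze_c1_alpha_coupling` traces the per-c1
argmin over alpha of a single-frame objective on a (c1, alpha) grid and
fits the log-linear law `a log c1 + log alpha = log b`, reporting the
coupling constants, the valley, and a flatness measure; it is the basis of
the landscape validation below. `fit_exponential_decay` fits
`A exp(-t/tau)` to a tension profile by a log-linear solve on the strictly
positive points.

## Synthetic validation

The in silico harness generates diastolic series with the package's own
forward model — a deliberate inverse crime that isolates the correctness
of the estimation algorithm from model fidelity. The reference experiment
has six frames, linearly increasing pressure (0.33, 0.67, 1.00, 1.33,
1.67, 2.00 kPa) and exponentially decaying AT (8.00, 2.35, 0.68, 0.21,
0.05, 0 kPa), noiseless by default; optional isotropic Gaussian
displacement noise (seeded, applied to observed positions only) supports
robustness sweeps. The first frame carries the minimum (nonzero) pressure;
the zero-pressure convention for the first frame is relaxed to "minimum"
for generated cases.

The default constitutive truth is `c1 = 1`,
`alpha = exp((19/31) ln 400) ≈ 39.35`, `r3 = 0.25`, `r4 = 0.30` — the
healthy-myocardium magnitude, placed exactly on the estimator's default
sweep lattice (nearest lattice point to the healthy estimate
`alpha = 42.56, r3 = 0.2507, r4 = 0.2998`). A lattice-representable truth
makes noiseless self-recovery limited only by the algorithm, not by grid
quantization.

Six scenarios probe the two structural choices of the pipeline: (1) k = 1
without deflation, (2) k = 1 with deflation, (3) criterion k without
deflation, (4) the full pipeline, (5)/(6) one frame before/after scenario
4's k, with deflation. Each is scored by the RMSE between estimated and
true AT over frames 1..n−1.

What passing these tests shows — and what it does not: the synthetic data
share the estimator's forward model, geometry and fiber field, so the
tests validate the estimation *algorithm* (sweeps, deflation, criterion,
bookkeeping), not the fidelity of the reduced LV model to real
myocardium, and not robustness to registration noise structure, model
error, or patient anatomy.

## Known limitations

* The observed-frame reference approximation biases the constitutive
  estimate: the frame-k cloud is pre-strained by the very tension being
  estimated, and because softening the fiber direction mimics residual AT
  (the same confound the clinical analysis reports for early-diastolic
  frames), the anisotropy fractions absorb part of that pre-strain. In
  the reference experiment this depresses the early-diastolic tension
  estimates by roughly 10–30% even though end-diastole is matched exactly;
  the accuracy claims of the acceptance suite record this honestly.
* The anisotropy fractions are weakly identifiable from a single frame in
  this reduced kinematic family: the (r3, r4) valley of the end-diastolic
  objective is shallow, so off-lattice truths are recovered to within
  about one grid cell, not to the cell.
* The reduced model has no right ventricle, pericardium, atrium, long-axis
  shear or patient geometry; the base plane is rigidly fixed; negative
  estimated tensions (allowed by the sweep range) are recorded and
  flagged, not interpreted.
* Pressure calibration follows the convention that minimum diastolic
  pressure defines the zero level.
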