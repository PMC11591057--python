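# Methods

`eegbem` implements a complete forward/inverse accuracy study for EEG dipole
source localization on layered volume-conductor head models: a charge-based
boundary-element forward solver with adaptive mesh refinement generates
"ground-truth" electrode voltages, a classical potential-based three-layer BEM
fits single dipoles to those voltages, and the position/orientation
discrepancies quantify how much the two modeling chains disagree.  Synthetic
concentric-sphere models stand in for MRI-derived head meshes, which also
makes a closed-form solution available as an independent accuracy oracle.

## Forward model: charge-based BEM

In the quasi-static regime a point current dipole with moment `q = I0 d`
(A m) embedded in a medium of conductivity `sigma_src` creates the impressed
potential

    phi_i(r) = q . (r - r0) / (4 pi sigma_src |r - r0|^3),

and the total field separates as `E = E_i + E_s`, where the secondary field
arises from surface charge deposited on every conductivity discontinuity.
On each interface with inside/outside conductivities `sigma-`/`sigma+` and
contrast `K = (sigma- - sigma+)/(sigma- + sigma+)`, the charge density rho
satisfies a second-kind integral equation; collocation at facet centroids
with a per-facet constant charge basis gives, at facet m,

    rho_m/(2 eps0)
      - K_m n_m . sum_{n != m} rho_n A_n (r_m - r_n)/(4 pi eps0 |r_m - r_n|^3)
      = K_m E_i(r_m) . n_m .

The dipole medium conductivity is the grey-matter value of the conductivity
set (the BRAIN value for three-layer models), exposed as
`LayeredHeadModel.source_conductivity`.  `eps0` cancels exactly between the
solved charge and the evaluated potentials; it is kept only to keep rho in
C/m^2.

**Near-field integration.** The point-panel (centroid) kernel above is exact
in the limit of well-separated panels, but head models put adjacent
interfaces (skin-skull, skull-CSF, CSF-GM gaps of ~2-6 mm) within about one
panel size of each other at working resolutions.  There the centroid kernel
is the dominant error source: on a three-layer sphere at 5120 facets/layer it
alone accounts for roughly half of the electrode-voltage error against the
analytic solution (RDM 0.062 vs 0.034 without refinement).  Facet pairs whose
center distance is below `NEAR_FIELD_FACTOR = 3` times the larger panel size
are therefore integrated with a 64-point midpoint rule over congruent
subtriangles of the source panel; the operator remains a pure collocation
method (one equation per facet centroid).  Setting `near_field=0` recovers
the literal point-panel equation.

**Linear solver.** The system is solved with unrestarted GMRES (`restart`
equal to the 300-iteration cap) at a relative residual tolerance of 1e-5.
Restarted GMRES(30) stagnates around 1e-4 on high-skull-contrast models
(`|K| ~ 0.96`), which is why the restart default equals the cap; both remain
configurable.  Up to `DENSE_LIMIT` facets the scaled operator (diagonal 1) is
assembled densely — `M^2` kernel evaluations cost about as much as three
matvecs, after which each GMRES iteration is a BLAS gemv — and above the
limit an on-the-fly matvec kernel plus a sparse near-field correction is
used.  A dense direct (LU) path exists as a reference for solver-equivalence
checks.

GMRES actually iterates on the diagonally similar system `D A D^-1` with
`D = diag(A_m / mean(A))`: the residual then measures the area-weighted
(Galerkin-consistent) norm of the residual function while the eigenvalues —
and hence the convergence behavior — are exactly those of the unscaled
operator.  This matters once AMR has produced panel areas spanning several
orders of magnitude: in the unweighted norm the tiny near-source panels
dominate the residual, and two iterates that both satisfy the 1e-5 tolerance
can differ by tens of percent in electrode voltages; in the weighted norm
the same tolerance pins the voltages to a few 1e-4 of a direct dense solve.

**Potential read-out.** Total potential is `phi_i` plus the single-layer
charge potential.  At a facet's own centroid the self term uses the analytic
constant-charge integral `int dA/|c - r'|` (per-edge `asinh` closed form);
electrode voltages are the potentials at the skin facets the electrodes are
assigned to.  Voltages are stored raw (single-ended); every comparison and
the fitting pipeline use average-referenced vectors, since an EEG potential
is only defined up to a reference.

## Adaptive mesh refinement

Conventional AMR subdivides the top 1% of facets by total charge magnitude
`C_m = |rho_m| A_m` into four congruent midpoint children, re-solves, and
stops when the relative change of the electrode-voltage vector between steps
falls below 1% (at most 12 steps).  The stopping norm is evaluated on
average-referenced voltages: the single-ended read-out carries a large
common-mode level (for deep radial dipoles ~97% of the raw norm) that keeps
drifting with refinement and otherwise stalls the criterion without changing
any referenced quantity.  With referencing, sphere runs converge in 4-6 steps
for mid-depth dipoles, rising toward the 12-step cap only for sources close
to an interface.  The skin surface is never refined (it is the read-out
region); children lie in the parent's plane, so total area and enclosed
volume are conserved exactly, and the resulting hanging nodes are admissible
for the per-facet constant basis.

b-refinement replaces the solved charge by its zero-order surrogate, the
impressed-field magnitude `C_m = |E_i(r_m)| A_m`, so refinement passes need
no intermediate solves; a single full solve finishes.  The number of passes
defaults to 6 (roughly the conventional step counts observed on spheres); an
explicit stopping rule for b-refinement is not part of this package.

A desk-scale property worth knowing: with the near-field-corrected operator,
conventional AMR step counts are driven mostly by the global resolution of
the thin shells rather than by source depth (a 50%-depth and a 90%-depth
dipole converge in nearly the same number of steps), because the per-facet
charge cost sends a sizable share of the refinement budget to the
high-contrast skull and CSF interfaces everywhere, not only near the source.

Implementation note: refinement replaces each subdivided parent's facet slot
with its first child and appends the rest, so the dense operator can be
updated incrementally (only changed rows/columns recomputed) and per-dipole
refinement runs can share one preallocated workspace buffer; each GMRES solve
warm-starts from the previous charge density with children inheriting their
parent's value.  None of this changes results beyond solver round-off.

## Analytic oracle

For concentric spheres the scalp potential has a Legendre-series solution.
With the dipole at radius `b` on the local z axis, the potential is expanded
per degree l in each shell as `a_l r^l + b_l r^-(l+1)` plus the known dipole
expansion in the source shell; continuity of potential and radial current at
every interface and zero current into the air close the system.  The source
may sit in the core or in any interior shell — the latter is essential for
validating midsurface (GM-shell) dipoles — with the source expansion taking
different radial profiles above and below `b` and between the radial-moment
and tangential-moment azimuthal orders.  Each shell's solution is
parametrized with radius ratios <= 1, so the per-degree linear systems stay
well conditioned to high order; truncation defaults to L = 60 (changes
< 1e-8 beyond L = 40 for dipoles at 70% depth; use L ~ 100 for high-contrast
five-layer shells).  The series was validated to 1e-8 against an independent
closed form for the homogeneous sphere (summed generating functions), to
machine precision against the infinite-medium dipole potential, and — for
shell sources — against the equal-conductivity reduction to the homogeneous
sphere.

## Inverse model: potential-based three-layer BEM and dipole fitting

The inverse engine mirrors the classical three-layer BEM used by standard
EEG toolboxes.  Interface potentials satisfy the piecewise-homogeneous
double-layer relation

    (sigma- + sigma+)/2 phi(r) = sigma_src phi_inf(r)
        + 1/(4 pi) sum_j (sigma_j- - sigma_j+) int_{S_j} phi dOmega_r ,

discretized by centroid collocation with exact van Oosterom-Strackee solid
angles.  With an insulating exterior the system has the constants in its
nullspace; Lynn-Timlake deflation (adding the mean projection) removes the
rank deficiency, and all downstream quantities are average-referenced.  An
`outer_conductivity` parameter exists chiefly to realize the zero-jump
identity test (equal conductivities everywhere reproduce the infinite-medium
potential exactly).

One LU factorization per model yields an electrode transfer matrix
(`voltages = T . source-term vector`) via a multi-right-hand-side transposed
solve, after which a leadfield at any source position costs two small
matrix products.  Single-dipole fitting minimizes the residual variance

    RV(p) = ||V - L(p) q_hat(p)||^2 / ||V||^2,

with the moment `q_hat` obtained by ordinary least squares from the 3-column
leadfield (no regularization; the data are noiseless).  Two strategies are
implemented: a derivative-free Nelder-Mead simplex started from a given
point (position tolerance 1e-5 m, at most 400 evaluations), and a 5 mm grid
scan over all positions inside the innermost (BRAIN) surface followed by the
same simplex refinement from the best node; when both run, the lower-RV fit
is reported.  Grid leadfields are precomputed once per model through the
transfer matrix.  Positions outside the innermost surface are rejected with
a distance penalty during the search.

The source grid is restricted to the innermost surface (the brain
compartment): that is where the leadfield model is valid, and it matches the
"inside" definition used by the standard source-model preparation in EEG
toolboxes.

## Synthetic geometry

Icosphere-based concentric shells emulate the study geometry: a five-layer
skin/skull/CSF/GM/WM stack with default outer radii 92/86/80/78/72 mm and a
three-layer SKIN/SKULL/BRAIN stack (92/86/80 mm).  The radii are a design
choice respecting anatomical shell thickness ordering; they are not fitted
to any dataset.  Conductivity sets: three seven-compartment tables (VWB7,
IT'IS7, SimNIBS7, including cerebellum/ventricle/eye values for
completeness even though the synthetic shells do not instantiate those
compartments) and their matched three-layer reductions (VWB3, IT'IS3,
SimNIBS3).  Dipoles are placed on the midsurface between the CSF-GM and
GM-WM interfaces (for spheres, the nearest-point and normal-shooting
midsurface definitions coincide) and oriented along the outward normal of
the nearest CSF-GM facet; well-separated placements use k-means clustering
of facet centers snapped back to the surface.  Electrodes (default 256) are
a Fibonacci lattice on the bounding sphere snapped to distinct nearest skin
facets, so the assigned facet center is exactly the electrode position.

What the synthetic data do not emulate: cortical folding (sphere leadfields
are smoother and better conditioned than real anatomy), mesh decimation
artifacts, segmentation differences between pipelines, electrode-placement
uncertainty, and measurement noise.  Passing the synthetic checks therefore
demonstrates the numerical fidelity of both solvers and of the fitting
machinery on matched geometry — not localization accuracy on real heads.

## Problem sizes and reproduction

The shipped study sizes are chosen for a single-CPU desk run.  The
three-layer self-consistency experiment uses subdivision-4 icospheres
(5120 facets/layer, 15360 facets total) with 10 mixed radial/tangential
dipoles at 50-90% of the inner radius — a deliberate scale-down of the
study's ~14,000 facets/layer decimated meshes.  The four-layer
solver-vs-oracle validation in the test suite also runs at subdivision 4.
At these sizes the full `scripts/acceptance.py` run completes in roughly
13 minutes on one CPU.  Observed behavior at this scale: mean AMR step
counts ~5, mean position recovery error ~0.9-1.0 mm, mean orientation error
~0.1-0.2 degrees, residual variances ~2e-4 (all recomputed by the
acceptance script, not stored).

## Why the five-layer b-refinement comparison does not scale down

The five-layer comparison (b-refinement vs conventional AMR, identical
geometry and dipole) is reported by the acceptance script at 1280
facets/layer with the conventional reference run to actual voltage-change
convergence (which takes ~27 rounds at that density; the 12-round guard is
raised to 30 for this run only).  The resulting discrepancy — RDM ~50%,
relative 2-norm ~80% — is far beyond the few-percent agreement reported for
high-resolution head models, and deliberately so: it is the honest outcome
of the scale reduction, not a solver defect.  Three measurements support
this reading.  First, the base five-layer solution at this density is ~140%
RDM from the analytic shell-source solution: the 2 mm CSF-GM gap would need
~1.6 mm panels (icosphere subdivision 6, ~82k facets/layer) to be resolved,
so every desk-scale base mesh starts qualitatively wrong.  Second,
conventional AMR repairs that error globally — skull and CSF facet counts
roughly triple, far from the source — because the charge cost is large on
the high-contrast interfaces everywhere; it converges to ~0.40 RDM from the
oracle.  Third, b-refinement ranks facets by the impressed field, which
decays as distance cubed from the dipole, so it only ever refines the
near-source patch and stays ~0.5 RDM from the oracle no matter how many
passes run (6-24 were measured).  The two strategies agree to a few percent
only when the base mesh is already fine enough that both refinements are
small local corrections — the regime of the original claim, out of reach at
desk scale.  The solver chain itself was cross-checked at every step: the
shell-source oracle reduces to the homogeneous-sphere closed form to machine
precision, the incrementally updated operator matches a fresh assembly to
3e-18, and warm-started solves match fresh solves to ~1e-3.

## Numerical choices and limitations

- Ties in top-1% cost selection break by ascending facet index
  (determinism); all stochastic placement is driven by a single integer
  seed through `numpy.random.default_rng`.
- GMRES tolerance 1e-5, interpreted as a relative residual (dimensionless);
  an absolute threshold would not transfer across mesh densities or dipole
  moments.
- The forward electrode read-out keeps the centroid single-layer sum plus
  the analytic self term; near-field quadrature in the read-out was measured
  to change electrode RDM by < 2% of its value and is omitted.
- The charge solver's accuracy for sources closer than ~1 panel size to an
  interface is limited by the constant-charge basis itself; AMR mitigates
  but does not remove this.
- No noise modeling anywhere: the study design is noiseless single-sample
  EEG.
- Anisotropy, MEG, distributed sources, and multi-dipole fits are out of
  scope.
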