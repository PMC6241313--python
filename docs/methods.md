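# Methods

## Shape space and deformations

Shapes are triangulated surfaces in a common millimetre frame, compared
through diffeomorphisms of the ambient space (the LDDMM model).  A
deformation is the endpoint of a flow of time-dependent velocity fields
v(., t) living in a reproducing-kernel Hilbert space V with kernel
K_V(x, y) = h(||x−y||²/σ_V²)·I₃; by default h is the Cauchy profile
1/(1+r).  Optimal deformations of a mesh are parametrized by one momentum
vector α_p per vertex: the coupled Hamiltonian system

    dx/dt = K_V(x) α,     dα/dt = −½ ∇_x [αᵀ K_V(x) α]

is integrated from (x(0), α(0)) (geodesic shooting), and the conserved
Hamiltonian αᵀK_V α equals the squared geodesic distance D(id, φ)².  The
initial momenta are therefore both the optimization variable of matching
and the tangent-space coordinates used by all statistics.

Integration uses the explicit trapezoidal (Heun) rule with T = 10 uniform
steps by default (configurable).  Heun is second order; with the moderate
deformations used here (‖α‖_K ≲ σ_V) the Hamiltonian drifts by well under
1% over the unit interval at T = 20, which the test suite asserts.
Off-trajectory points are carried by integrating dy/dt = Σ_p K_V(y, x_p(t))
α_p(t) with the same rule; reverse-time transport re-integrates the ODE
backwards rather than inverting a map.  States at off-grid times are
linearly interpolated between grid states — an O(dt²) error consistent
with the integrator order; the centroid recursions use times 1/(k+1) that
rarely sit on the grid, and tests that need exactness choose T so they do.

## Currents data term

A surface acts on a vector field by integrating its normal component; this
linear functional (a current) is discretized as one vectorial Dirac per
triangle, placed at the barycenter and weighted by the area-scaled normal
½(v₁−v₀)×(v₂−v₀).  The W* inner product of two surfaces is then a closed
double sum through a second Cauchy kernel of width σ_W.  This metric needs
no point correspondences, is robust to remeshing (the suite checks a 1→4
subdivision changes a norm by <2% when σ_W is at least the mean edge
length), is orientation-sensitive, and — crucially for the IC2 and
template estimators — makes weighted unions of surfaces first-class
citizens: they enter matching only through inner products.  Barycenter
placement (rather than vertices) is the standard discretization and the
one that converges under refinement.  Tiny negative squared distances from
floating-point cancellation are clamped at zero, with a warning beyond
−1e−8 of the self-inner-product.

## Matching

The matching functional J(v) = γE(v) + ||[φ_v(S)] − [T]||²_{W*} is
minimized over the initial momenta α(0) attached to the source vertices:
the optimum of the time-dependent problem is a geodesic, so shooting loses
no generality and shrinks the unknowns to 3n numbers.  E(v) is then
α(0)ᵀK_V α(0).

Gradients are exact: the currents term is differentiated analytically with
respect to the endpoint vertices (chain rule through barycenters and cross
products), and the result is pulled back through the Heun steps by a
hand-coded adjoint sweep using the vector-Jacobian product of the geodesic
right-hand side (first and second derivatives of the kernel profile).
The test suite verifies every piece against central finite differences to
~1e−7 relative.  Hot loops (geodesic RHS, its VJP, the attachment term)
have numba-compiled twins that the tests assert equal to the numpy
reference at machine precision.

The optimizer is L-BFGS (scipy) with a multiscale schedule on σ_W —
default [σ_W, σ_W/2] with σ_W = σ_V/2 — warm-starting each scale from the
previous optimum.  Coarse scales pull surfaces together globally before
fine scales resolve detail, which in practice avoids the poor local minima
of the non-convex functional.  Defaults: γ = 0.1, 100 L-BFGS iterations
per scale, relative tolerance 1e−6.  The iteration cap was profiled on
ground-truth recovery problems (a target generated by shooting known
momenta of norm 0.5σ_V): between 100 and 200 iterations the recovered
distance changes by <0.1% while cost doubles, so 100 is the default; all
of this is config-overridable.  Self-matching recovers near-zero momenta,
and known-momenta targets are recovered with distance error well inside
15%.

## Centroid estimators

All three estimators decompose the running-mean recursion
b_{k+1} = (k·b_k + x_{k+1})/(k+1) into pairwise geodesic convex
combinations, at exactly N−1 matchings:

* **IC1** keeps a single mesh: match the centroid to the next subject and
  flow it to t = 1/(k+1).  The centre is a deformation of the first
  subject, so the result depends on the ordering (always recorded; default
  input order, seeded shuffle available).
* **IC2** keeps a weighted union of surfaces in current space: members
  flow forward to the meeting time 1/(k+1), the new subject flows
  *backward* along the same matching flow (reverse-time transport of its
  vertices), and all members end with weight 1/N.  Matching shoots from
  the union's full vertex set, which is why IC2 costs more; memory grows
  linearly with processed subjects and no pruning is applied.
* **PW** recursively halves the population (left subtree gets the extra
  subject when odd) and combines subtree centroids of sizes n_a, n_b at
  t = n_b/(n_a+n_b).

A matcher hook lets tests substitute an exact Euclidean translator; under
it all three recursions return the arithmetic mean exactly, pinning the
weights independently of matching accuracy.

The variational template baseline alternates subject→template matchings
with the closed-form update (the template minimizing the sum of squared
W* errors is the average of the deformed currents), at N matchings per
outer iteration; defaults are 5 outer iterations with centroid
initialization and 8 with the standard all-subject average start.

## Tangent-space statistics

Momenta from a mesh centre to the subjects come from direct
centre→subject matchings and share the centre's vertices.  For collection
centres (IC2, template), matching each subject to the centre-current and
reversing (−α(1) at the transported vertices) avoids shooting from the
union; the per-subject point sets then differ, and all fields are
kernel-interpolated onto the first subject's transported points by solving
K(X,X)α̂ = v_i(X) with a 1e−10·trace ridge (logged loudly).  This
preserves each initial velocity field rather than its raw coefficients.

Kernel PCA eigendecomposes the N×N matrix
C(i,j) = (αⁱ−ᾱ)ᵀK_V(x)(αʲ−ᾱ)/(N−1), symmetrized to kill floating-point
asymmetry.  Modes are shot geodesically for visualization with the
deviation normalized to unit K-norm so amplitudes read as geodesic
distances.  The centring ratio R = ‖Σ vⁱ(·,0)‖_V / Σ‖vⁱ(·,0)‖_V is 0 at a
critical point of the Fréchet functional and ≤1 by the triangle
inequality; it is reported as undefined when all momenta vanish.
Approximated pairwise distances are first-order: the K-norm of momentum
differences at the centre (N matchings instead of O(N²)); direct matrices
match i<j only and mirror, since matching is not exactly symmetric.  The
matrix discrepancy e averages |M₁−M₂|/max(M₁,M₂) over all N² entries with
0/0 terms defined as 0.

The regression layer predicts a per-subject scalar score from centred,
unit-variance mode coordinates by ordinary least squares, reporting R²,
adjusted R² = 1 − (SSE/(N−p))/(SST/(N−1)), F = (R²/p)/((1−R²)/(N−p−1))
with its F(p, N−p−1) tail probability, and MSE = SSE/N.  Cross-validation
follows the repeated random hold-out design (each repeat predicts k
held-out subjects from the other N−k); a classical partition k-fold is an
option.

## Synthetic populations

The generator produces populations whose exact centre is known: momenta
αⁱ = k₁β₁ + k₂β₂ + k₃β₃ with k_j ~ N(0, σ_j), β₁ ⊥ β₂ (Euclidean
orthogonalization of stacked coordinates by default; K-orthogonality
optional), each β normalized to unit K-norm, and the second half of the
population exactly antipodal (α^{i+N/2} = −αⁱ), so Σα = 0 and the base
shape is the exact Fréchet-type centre by construction.  Shapes are
generated by shooting and carrying the base mesh.

Defaults emulate a hippocampus-scale study: the base shape is a 162-vertex
bent ellipsoid with semi-axes (15, 6, 5) mm and a gentle quadratic arc
(length ≈ 30 mm), σ_V = 15 mm (about half the shape length), σ₁ = 0.30σ_V,
σ₂ = 0.21σ_V, σ₃ = σ₂/20 (a two-dimensional shape space plus weak noise).
Mode-coefficient draws at these scales give subject-to-centre distances of
roughly 0.1–0.7 σ_V — visibly deformed but comfortably diffeomorphic.  A
finer 642-vertex base is available.

What the generator does *not* emulate: segmentation noise, varying mesh
connectivity across subjects, rigid-alignment residuals, and populations
whose variability is not generated by geodesics from a single shape.
Passing tests on these populations therefore demonstrate correctness of
the estimators and statistics under the model's own assumptions, not
robustness to real acquisition artifacts.

## Problem sizes and observed behavior

The end-to-end experiment sizes used by the bundled tests and the
reproduction script are 5 populations of N=10 subjects on 162-vertex
meshes (centring ratios, distance matrices) and one N=50 population for
the PCA-concentration check.  At these sizes a full matching takes a few
seconds on one core.

Two observations matter when comparing centring ratios across studies.
First, the ratio at the *exact* centre is a pure matching-noise floor:
with the exact adjoint gradients and the L-BFGS settings above we measure
R ≈ 0.02 on N=10 populations, and every downstream ratio scales with this
floor — more accurate matchings make every estimated centre look better
centred.  Second, the ratio *decreases* with population size: the
numerator averages N per-subject momenta whose error components partially
cancel, so on a single N=50 population the IC1 and PW ratios drop well
below their N=10 values (we measure R ≈ 0.007 and 0.013 respectively).
Centring ratios are therefore comparable across studies only at matched
population size and matched matching accuracy.

## Known limitations

* Matching is non-convex; the multiscale schedule is a heuristic and a
  poor σ_W (≫ or ≪ the shape scale) can stall the optimization.
* Momenta live on mesh vertices; there is no control-point decoupling, so
  cost scales with vertex count squared.
* IC2's collection grows linearly; for large N the union becomes the
  dominant cost, as reflected in its estimator.
* `flow_at_time` interpolation is only O(dt²); applications needing exact
  intermediate states should pick T so the needed times are on-grid.
* The identity-kernel family exists for test oracles only; it is not a
  smooth RKHS kernel and cannot be used for shooting.
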