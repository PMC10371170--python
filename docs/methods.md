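# Methods

## Physical model

Under the quasistatic approximation, the electric field a TMS coil induces
in a piecewise-homogeneous volume conductor is the sum of the coil's
primary field and the Coulomb field of charges induced on the conductivity
interfaces:

    E(r) = E_p(r) + (1/4πε₀) ∫_S ρ(r′) (r − r′)/|r − r′|³ dS′.

The primary field is the time derivative of the coil's magnetostatic
vector potential. A coil is modeled as a cloud of elementary straight
current elements (position `r_j`, moment `m_j` = direction × length ×
winding weight), giving

    E_p(r) = −(μ₀/4π) (dI/dt) Σ_j m_j / |r − r_j|.

This is exact for polygonal windings in the quasistatic limit; skin-effect
or litz current redistribution can be encoded in the element weights.

Enforcing continuity of the normal current σ_in n·E_in = σ_out n·E_out at
every interface yields a Fredholm integral equation of the second kind for
the scaled charge density ρ* = ρ/ε₀:

    ρ*(r)/2 − K(r) n(r) · ∫_S (r − r′)/(4π|r − r′|³) ρ*(r′) dS′
        = K(r) n(r) · E_p(r),

with the conductivity contrast K = (σ_in − σ_out)/(σ_in + σ_out), |K| ≤ 1.
Everything downstream works with ρ* (units V/m), so ε₀ never appears in
assembled quantities — one less 8.85e-12 scale hazard.

Normal convention: facet normals point from the `in` tissue to the `out`
tissue; nested head compartments use outward normals with σ_in the
enclosed (inner) conductivity. The one-sided fields at an interface are
E_in/out = E_pv ∓ n ρ*/2, where E_pv is the principal-value field of all
charges (the local facet is a planar charge sheet).

## Discretization

Surfaces are closed triangle meshes with piecewise-constant ρ* per facet.
The equation is enforced per facet in the facet-averaged (Galerkin-style
outer integral) sense:

    A_mn = δ_mn/2 − (K_m/A_m) ∫_{t_m} n_m · F_n(r) dA,
    b_m  = K_m n_m · E_p(c_m),

where `F_n` is the field of facet n with unit ρ*. Choices that matter:

* **Self term.** For a flat facet the principal-value field in its own
  plane is purely tangential, so the self entry is exactly 1/2. This is
  asserted, not approximated.
* **Near pairs** (centroid distance ≤ 5 × √max(A_m, A_n), the default
  `near_threshold`): `F_n` is evaluated in closed form — for each edge a
  logarithmic potential term with the in-plane outward edge normal, plus
  the signed solid angle (van Oosterom–Strackee) for the normal part —
  and the outer facet average uses a 7-point degree-5 symmetric triangle
  rule. Plain centroid collocation was measured to lose roughly a factor
  4 of accuracy on sphere benchmarks (6.1% vs 1.4% charge-density error
  at 1280 facets); the 7-point outer average restores the behavior of the
  full double integral at ~7× the near-pair assembly cost.
* **Far pairs**: source facet collapsed to a centroid monopole, outer
  integral collapsed to the target centroid. At 5 facet-radii separation
  the committed error is below the discretization error; widening the
  near radius changed sphere results at the 1e-4 level only.
* **Right-hand side**: evaluated at centroids. The 7-point facet average
  of E_p shifts reference-case fields by ~0.08%, an order of magnitude
  below discretization error, and is omitted.
* The exactly in-plane solid angle is clamped to zero when the
  Van Oosterom triple product is below 1e-12 of its scale, so collocation
  points on their own facet get the principal value rather than a ±2π
  jump riding on float noise.

The operator exists in two interchangeable forms (verified to 1e-10
relative against each other):

* **dense** — the full N×N matrix (guarded by a configurable cap,
  default 60 000 facets), enabling LU factorization;
* **matrix-free** — a compiled (numba) direct-summation monopole matvec
  over all facet pairs plus a sparse near-field correction holding
  (analytic − monopole) entries. This is the desk-scale stand-in for an
  accelerated (FMM-type) far-field backend: the contract is just a
  matvec, so such a backend could be swapped in without touching the
  solvers.

## Solvers

The system is well conditioned (second-kind), so unrestarted GMRES from a
zero initial guess reaches a relative residual of 1e-6 in a few tens of
iterations; the implementation wraps `scipy.sparse.linalg.gmres` with the
restart length set to the iteration cap and re-verifies the true residual
after the solve. Default tolerance 1e-6, cap 200 iterations.

The direct path computes one pivoted LU of the dense operator per head
model (`scipy.linalg.lu_factor`) and reuses it for every coil pose — each
pose is only a new right-hand side and a pair of triangular solves. A
SHA-256 fingerprint of the geometry and conductivities binds a saved
factorization (HDF5) to its model; reuse with a different model raises.
An instrumentation counter exposes the factor-once contract to tests.

Refined ground-truth solves use nested iteration: each 1:4 refinement
level starts GMRES from the previous level's solution prolonged onto the
child facets. This shortens the Krylov sweep but cannot change the
answer, because the stopping test is on the true relative residual.

## Field evaluation

Off-surface fields sum the analytic triangle field for facets within 20
facet-sizes of the observation point and centroid monopoles beyond.
Evaluation cost is per point and small, so this radius is deliberately
wider than the assembly near radius: it keeps evaluation quadrature error
well below the charge-solve discretization error (with radius 5 the
coarse-level evaluation error measurably polluted refinement-convergence
ratios). Points within 0.1 facet-sizes of a surface are rejected by a
guard (the kernel is discontinuous there) and must use the one-sided
evaluator, which works at facet centroids and adds the exact ∓ n ρ*/2
sheet term. The guard uses nearest-centroid distance — cheap and adequate
for a guard, though a point can sit near a facet's rim yet far from any
centroid; such points evaluate accurately anyway since the near radius is
much wider than the guard.

The boundary-condition residual diagnostic normalizes the normal-current
mismatch by the local conductivity-weighted field magnitude
(σ_in + σ_out)(|E_in| + |E_out|)/2 rather than by the currents
themselves, which would be degenerate on an insulating exterior
(σ_out = 0 forces J_out ≡ 0). On solved sphere models the area-weighted
mean residual is ~1.6e-2 at 1280 facets and halves per 1:4 refinement.

## Synthetic study conditions and oracles

No external head data is used anywhere. The reference study is a
three-layer concentric-sphere head: radii 90/85/80 mm, conductivities
0.33/0.01/0.33 S/m (scalp-like, skull-like, brain-like; the standard
three-sphere volume-conductor idealization), icosphere meshes with 1280
facets per surface by default, and a one-turn 70 mm figure-8 coil (two
35 mm loops of opposite sense, 64 segments each) placed 5 mm above the
vertex with tangential coil plane, driven at dI/dt = 9.4e7 A/s — a
typical motor-threshold pulse. Observation points are ~1000 points on an
interior shell at 0.8 × the innermost radius, far enough from the surface
that evaluation error cannot contaminate solver comparisons; the "region
of interest" is a 4 cm diameter sphere around the probe point nearest the
coil center.

What the spheres do not emulate: cortical folding and the associated
strong local field gradients, thin and touching compartments (CSF), mesh
quality variation of segmentation-derived surfaces, and anisotropic
conductivity. Passing the sphere suite therefore validates the integral
formulation, the analytic integrals, the solvers and their equivalence —
not robustness to realistic head-model pathologies.

Three independent oracles check correctness:

1. **Uniform conservative field.** A conducting sphere in air exposed to
   a synthetic uniform field E₀ẑ (injected through a test-only excitation
   object; not realizable by any coil) has the closed-form solution
   ρ* = 3E₀cosθ with zero total interior field. At 1280 facets the solver
   recovers the density to 1.4% and cancels the interior field to 1.7% of
   E₀, both improving under refinement.
2. **Profile independence.** For inductive (closed-loop coil) excitation
   the interior field of a spherically symmetric conductor is independent
   of the radial conductivity profile, and its radial component vanishes.
   One-shell and three-shell models agree to well under 2% at matched
   resolution although their discretizations share no facets.
3. **Self-convergence.** A 1:16 uniformly refined (sphere-projected),
   tightly solved model serves as ground truth; the default-resolution
   error against it shrinks by well over 4× per 1:4 refinement step in
   the ROI.

The conservative and inductive cases behave oppositely in the interior
(full cancellation vs. persistent field), so the pair also verifies that
the solver distinguishes the two excitation classes.

## Numerical edge cases

* Degenerate facets (area < 1e-16 m², aspect ratio > 1e6) and non-manifold
  edges are rejected at validation; vertex welding tolerance on STL read
  is 1e-9 m.
* Observation points coinciding with a triangle vertex or riding on an
  edge raise explicit singularity errors; the edge-log terms switch
  between two algebraically equal forms for numerical stability.
* Orientation is validated via divergence-theorem closure and signed
  volume; inward-oriented interfaces either raise or are auto-flipped on
  request. Nesting is declared by the ordered compartment list, never
  inferred geometrically, so strictly valid closed surfaces are required
  (touching or intersecting interfaces are out of scope).
* SI units throughout (m, S/m, V/m, A/s); millimeter STL files are
  converted on read via the model file's `units` field.

## Problem sizes and costs

Defaults are chosen so every check runs on a single CPU core: the
reference model is N = 3840 facets (dense assembly ~10 s, LU ~10 s,
GMRES(1e-6) ~35 iterations), and the 1:16-refined ground truth is
N = 61 440, solved matrix-free in ~30 GMRES iterations at ~13 s per
direct-summation matvec. The dense cap (60 000) marks where dense storage
stops being sensible, not where the method stops working; the matrix-free
path has no such limit.
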