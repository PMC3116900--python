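# Methods

## Model

The canvas is a thin tissue: two triangulated surfaces A and B sharing one
index set, each midplane triangle extruded into a six-node linear wedge
element.  All regulatory quantities (factor concentrations, organiser
clamps, growth-rate fields) live on midplane vertices, reflecting the
assumption that concentrations do not vary through the thickness; mechanics
lives on the paired surface vertices so that bending is representable.

Growth is prescribed as *specified strain*: per element, per
through-thickness quadrature layer, the symmetric increment
`dt · (k∥ u⊗u + k⊥ v⊗v + k_n n⊗n)` in the frame spanned by the polarity
axis u, its in-plane perpendicular v, and the element normal n.  The rates
on the two surfaces interpolate linearly through the thickness; unequal
surface rates therefore load the two quadrature layers differently and
generate bending moments (curling, invagination).  Equilibrium is the
minimiser of the residual-strain energy
`½ ∫ (Du − ε_spec) : C : (Du − ε_spec) dV` (virtual work with no external
forces), an initial-strain finite-element problem `K u = f`.  Because every
force is the material acting against itself, multiplying C by any positive
scalar leaves u unchanged; only Poisson's ratio enters, and weakly (see
below).  Large growth is the accumulation of many small steps — a plastic
flow computed with small-strain elasticity.

Polarity is the (negated, normalised, in-plane-projected) gradient of the
POLARISER field.  Modes per element: `live` (follows the instantaneous
gradient), `frozen` (a material vector, convected by each step's
deformation gradient and re-projected), `external` (projection of a fixed
lab direction), `absent` (in-plane isotropic growth).  Shallow gradients
below a detection threshold either freeze the current axis (default) or
drop to isotropy; both options exist because cells cannot read arbitrarily
shallow gradients and the numerics cannot either.

Signalling factors obey `∂c/∂t = D∇²c + p − d·c` on the midplane (P1
elements, consistent mass, backward Euler by default; forward Euler with
lumped mass and a stability guard is available).  Dilution is a separate
bookkeeping step: after the mechanics, each dilutable concentration is
scaled by the ratio of its vertex control volume (lumped midplane area ×
local thickness) before/after the step, conserving Σc·V exactly.  Identity
factors are regional labels: never diffused, never diluted, carried by the
vertices they sit on.

## Simulation loop

Per step, in order: (1) interaction function (the user-supplied regulatory
networks; it may set rates, clamps, retention and polarity modes but is
forbidden — and checksum-checked — from moving vertices); (2) diffusion;
(3) specified-growth assembly; (4) elastic solve and vertex update;
(5) dilution; (6) remeshing check; (7) residual retention/discard and
polarity update; (8) time advance and snapshots.  Dilution uses control
volumes on the pre-remesh connectivity and runs just before the split pass:
splitting is interpolation-only for retained vertices, so this ordering
keeps the tracked mass exact while new vertices receive already-diluted
values.

The step size obeys `dt = min(dt_init, 0.10 / max|k|)` — at most 10%
specified growth per step — and any step whose resultant rotations exceed
10° anywhere is rolled back and repeated with dt halved.  Both caps are
configurable.

## Numerics

- **Element/quadrature**: isoparametric 6-node wedge; 3 in-plane points ×
  2 through-thickness Gauss points.  The two thickness points double as the
  layers at which specified growth and stored residual strain are sampled.
- **Constraints**: per-dof zero fixings eliminated through a reduction
  transform; the flatness condition (midplane stays planar, thickness free)
  is a multi-point constraint replacing each paired z-displacement by a
  single per-vertex thickness unknown (uzA = −h/2, uzB = +h/2).
- **Solver**: the reduced K is symmetric positive semidefinite with nullity
  ≥ 6 on an unconstrained mesh.  Default is a sparse direct solve of a
  bordered system in which the constraint-compatible rigid modes are pinned
  by Lagrange multipliers; this is deterministic and robust on
  bending-dominated thin sheets, where Jacobi-preconditioned Krylov methods
  stall.  `minres` and `cgs` (with Jacobi preconditioning and a
  least-squares fallback) remain selectable.  Relative tolerance 1e-6
  (RMS; max-abs selectable); diffusion tolerance 1e-4.  After every solve
  the free rigid modes are projected out, so results are reproducible
  across solvers.
- **Resultant growth**: per-element displacement gradient from the shape
  functions at the element centre; ε/ω as its symmetric/skew parts, with
  per-layer strains for residual bookkeeping.
- **Residual strain**: `residual = specified − resultant` per layer (what
  was asked for but not realised); compatible uniform growth then gives
  zero residual exactly.  Retention r ∈ [0,1] per element (r = 0 discards).
  Stored tensors are convected by each step's incremental rotation
  (conjugation; trace/determinant preserved).  Release is incremental:
  apply `fraction_per_iter` (default 0.1, matching the 10% small-strain
  rule) of the store as specified strain, solve, subtract the realised
  strain, rotate the remainder; terminate when motion stops or the store's
  energy stagnates (an incompatible remainder plateaus at positive energy).
  Energy decreases monotonically up to solver noise (~1e-5 relative).
- **Remeshing**: when any midplane edge exceeds the upper threshold
  (default 2× the initial mean edge length), all edges above the lower
  threshold (1.5×) are split.  New vertices use the 8-point butterfly
  stencil (½, ½ endpoints; ⅛, ⅛ apexes; −1/16 outer wings), applied
  independently to the two surfaces and to factor values; incomplete
  stencils (boundary neighbourhoods) fall back to the midpoint.  Identity
  factors are re-thresholded at 0.5 after interpolation to keep regions
  crisp; quality is maintained by min-angle-improving edge flips.  Clones —
  circles tracked as barycentric boundary points, diagnostics only — are
  re-anchored through the parent-element map.
- **Degenerate inputs**: zero-area triangles flag a zero gradient / raise a
  geometry error in frame construction; collinear clone point sets report
  an infinite anisotropy ratio; ν = 0.5 is rejected (the isotropic
  stiffness loses positive definiteness exactly there, verified by
  bisection).

## Open design choices

- **pro/inh**: `pro(k,x) = 1 + k·x`, `inh(k,x) = 1/(1 + k·x)` — the
  simplest pair that tends to 1 as x → 0, composes multiplicatively, and
  makes `inh` the exact reciprocal of `pro`.
- **Isotropic fallback** where polarity is absent: the mean of k∥ and k⊥
  (preserves specified areal growth); `kpar`/`kper` selectable.
- **Polarity sign**: the axis points down-gradient (away from plus
  organisers); growth is axial, so tensors are invariant under axis
  negation.
- **Through-thickness interpolation** of per-surface rates is linear — the
  minimal scheme that realises per-surface rates and bending with two
  quadrature layers.
- **Bow**: out-of-plane cases break the up/down symmetry with a C¹ cosine
  bump (peak = `bow` at the centre); only its sign matters.

## Poisson-ratio sensitivity

Displacements produced by a *compatible* specified strain are exactly
independent of ν (the strain is simply realised).  For incompatible growth
the equilibrium displacement depends on ν, but weakly: for the
differential-growth presets the field changes by ~1–3% (max norm) between
ν = 0.2 and ν = 0.4, while shapes are visually indistinguishable.  The
package therefore treats ν as a nuisance parameter fixed at 0.3; the test
suite asserts the ≤5% sensitivity bound and the exact stiffness-scale
invariance (~1e-12).

## What the presets emulate — and what they do not

The presets are idealised study conditions: structured meshes, clamped
organisers, noise-free rate fields, and growth magnitudes of order 1 per
unit time (flat-sheet cases) or ~0.018 per unit time (tube cases, run to
2.2× and 5× areal multiples).  Default resolutions (flat sheets 800
elements, tube ~2500) are chosen so each case completes in minutes on one
CPU; `resolution` is a parameter and the captioned mesh densities of
comparable studies (~3200–5600 elements) are reachable by raising it.  The
tests and the acceptance script use further-reduced sizes (squares of
~200–800 elements, tubes to ~2500) — these exercise the same operators at
coarser discretisation.  Passing them shows the machinery is correct and
convergent, not that any particular organism's growth is captured: real
tissues have measurement noise, heterogeneous material properties,
cell-scale granularity and contact, none of which are modelled.

## Known limitations

No collision detection (arching tube sides grow through each other, as the
case descriptions note); no thin-shell formulation (wedges need thickness
within ~10× of the in-plane element size); linear isotropic elasticity
only; no advection of signals by tissue motion within a step (a
second-order effect); edge splitting only (no coarsening).  The
residual-release loop assumes small per-iteration strains; releasing very
large stores simply takes more iterations.
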