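# Methods

## The geometric question

Coronary atherosclerotic plaques of very different sizes turn out to be
geometrically consistent: across a population, pairs of their
multidimensional measurements (volume V, surface area S, length L,
on-surface distance, maximal cross-section) follow allometric power laws
`y = c·xᵉ` whose exponents are tightly bracketed.  `plaquegeom` provides
the modelling side of that observation — two idealized shell models with
closed-form geometry and growth hypotheses whose limiting exponents form
the bracket — together with the measurement machinery (mesh morphometry,
HU-threshold extraction from CT-like voxel grids) and the regression
layer needed to estimate the same exponents from data.

## Shell models

Both models are portions of a cylindrical shell of uniform thickness
wrapped around the artery lumen, parameterized in mm and radians.

**Model 1 — slanted full ring** (mature plaque): external radius `R`,
internal radius `r`, height `h` on the centerline, end planes slanted by
dihedral angles `θ1, θ2`.  Both planes tilt about the same transverse
axis, so the maximal axial extension lies on one side of the wall
(`x = +R`); the planes pass through the centerline at `z = ±h/2`, which
is why slanting leaves the volume unchanged:

    V  = π h (R+r)(R−r)
    S  = π (R+r) [2h + (R−r)(sec θ1 + sec θ2)]
    S/V = 2/(R−r) + (sec θ1 + sec θ2)/h
    L_wall  = h + R(tan θ1 + tan θ2)                (along the external wall)
    L_cross = √((2R)² + (h + R tan θ1 − R tan θ2)²) (diagonally across)

A realizable solid additionally requires `h > R(tan θ1 + tan θ2)` (the
end planes must not intersect inside the shell).  The slant-growth
trajectory below violates this beyond a finite scale while the algebra
stays well defined, so the parameter type supports a non-strict mode
used only on growth trajectories; mesh generation always enforces the
strict constraint.

**Model 2 — partial ring** (early patchy plaque): same `R, r, h` with a
circumferential angular extent `θ ∈ (0, 2π]`, flat perpendicular ends
and two flat radial side faces:

    V  = (θ/2) h (R+r)(R−r)
    S  = θ h (R+r) + 2h(R−r) + θ(R²−r²)
    S/V = 2 [ 2/(θ(R+r)) + 1/h + 1/(R−r) ]
    L  = √(h² + (2R sin(θ/2))²)                     (chord between far corners)

At `θ = 2π` the side faces vanish; the `2h(R−r)` side-face term is kept
so `S(θ)` is the continuous limit of the partial-ring formula, and a
degeneracy warning is emitted.  When the grouped numerator of
`ln S / ln V` is needed, it is `2h(R−r) + θ(R+r)(R−r+h)`, re-derived
from this surface decomposition.

## Growth hypotheses and exponent limits

A growth hypothesis prescribes how parameters co-vary with a scale
factor `k ≥ 1`:

| tag  | rule | S–V limit | L–V limit |
|------|------|-----------|-----------|
| H1.1 | R, r, h ∝ k; angles fixed | 2/3 | 1/3 |
| H1.2 | R, r, h ∝ k and sec θᵢ = k·sec₀ | 1 | 2/3 (wall) |
| H2.1 | R, r, h ∝ k; θ(k) = 2π − (2π−θ₀)/k | 2/3 | 1/3 (chord) |

The H2.1 schedule is one monotone smooth approach of θ to 2π; any
bounded monotone schedule yields the same limits, this one is
invertible.  Exponents are estimated numerically as the finite-difference
slope `Δln S / Δln V` (or `Δln L / Δln V`) between the two largest
scales of a geometric grid in `[1, k_max]` — the same estimator applies
unchanged to measured populations, unlike a symbolic limit.  Under H1.1
the slope is exactly 2/3 (S–V) and 1/3 (L–V) at every scale; H1.2 and
H2.1 converge at rate O(1/k), so `k_max = 1e6` puts the estimate within
1e-5 of the limit (tolerance used: 0.01).

Exponents fitted on a real plaque population (0.741 for S–V, 0.414 for
L–V) fall inside the bracket, within 0.08 and 0.09 of the lower bounds —
`verify_models()` recomputes this comparison.

Two boundary behaviours worth noting, because they are easy to
mis-state:

* S/V is strictly decreasing along every growth trajectory, but it only
  vanishes under H1.1 and H2.1.  Under H1.2 the secant-driven end-face
  area scales like the volume and S/V → 2·sec₀/h₀ (0.4 for the default
  base).
* The L–V slope stays inside [1/3, 2/3] on Model-1 trajectories; the
  H2.1 chord slope transiently drops below 1/3 while θ is still opening
  (the chord saturates as the ring closes) before converging to 1/3.

## Mesh synthesis and morphometry

Shell meshes are produced by sweeping the closed radial/axial profile of
the wall around the axis: a periodic sweep (torus topology, Euler
characteristic 0) for Model 1, a capped partial sweep (sphere topology,
χ = 2) for Model 2.  Resolution is `(n_circ, n_axial, n_radial)`;
discrete V and S converge monotonically to the closed forms (0.5% at
256×64×8, the resolution used for oracle tests).  Calcifications are
subdivided icospheres scaled to ellipsoid semi-axes with seeded,
neighbour-smoothed radial noise; amplitudes below 0.5 keep the surface
star-shaped, hence watertight.

Morphometry of a watertight mesh:

* **volume** — signed tetrahedron sum (divergence theorem);
* **surface area** — triangle-area sum;
* **length** — mesh diameter, computed exactly on convex-hull vertices.
  "Proximal/distal ends" are thereby operationalized as the
  max-distance pair, which coincides with the visual ends for elongated
  shells and is deterministic;
* **surface distance** — shortest path on a Steiner-refined surface
  graph (vertices + edge midpoints, complete within each face) via
  sparse Dijkstra.  Accuracy is 1–2% against unrolled-cylinder closed
  forms on near-isotropic meshes; strongly anisotropic triangulations
  degrade it (the graph metric tends to taxicab), so synthetic meshes
  are generated near-isotropic.  When several vertex pairs tie for the
  diameter (symmetric shells), the profile reports the minimum geodesic
  over the tied pairs, making it invariant to rigid motion;
* **cross-section** — at equally spaced stations along the centerline
  the mesh is sliced perpendicular to the local tangent (central
  differences; one-sided at the ends); the enclosed area uses even–odd
  accounting over the closed section loops, so full-ring sections
  subtract the lumen hole.  The maximal-area station also reports the
  longest in-section distance as the cross-section diameter.
  Calcifications carry no centerline and no cross-section fields.

Geodesic dominance (`surface_distance ≥ length`) holds by the triangle
inequality for every measured object and is asserted throughout.

## Phantoms and two-step extraction

Phantoms are HU-valued voxel grids (voxel-center convention,
`world = origin + index·spacing`).  Rasterization slices each watertight
mesh at every z-row of voxel centers and tests in-plane centers against
the closed section loops with even–odd parity — exact for voxel centers
and independent of any spatial-index or ray-casting backend.  Labels are
painted lumen → non-calcified → calcified, ground truth is recorded,
then the HU grid is degraded by a Gaussian point-spread blur
(`blooming_sigma`, mm — emulating calcium blooming) and seeded Gaussian
noise (`noise_sd`, HU).  Default tissue HU: background 40, lumen
(contrast) 400, non-calcified plaque 80, calcium 700.

Extraction mirrors the clinical two-step threshold procedure: calcified
voxels first (default interval `(150, 1334]` HU), then non-calcified
candidates (`(0, 150]`); intervals are half-open `(lo, hi]`, so exactly
150 HU counts as non-calcified.  Components are 26-connected; the union
of lumen-range, non-calcified and calcified masks, closed with a
1-voxel structuring element, is the outer boundary wrapping lumen and
plaque.  Components are surfaced by marching cubes (mask zero-padded so
edge-touching components close) and measured like any other mesh.  The
manual boundary revision used on real scans is replaced by a
quantitative error report (per-object relative volume error and Dice
against ground truth) — that replacement is deliberate: it turns an
operator step into a measurable one.

Two numerical details matter for accuracy: voxel centers falling
*exactly on* a flat face count as outside, so grids are laid out with a
half-voxel origin offset; and thin shell walls need ≥ 6 voxels across
the thickness for the full loop (rasterize → extract → marching cubes →
measure) to stay within 5% in volume — measured ≤ 3% with Dice 1.0 over
24 synthetic plaques at `spacing = min(0.25 mm, (R−r)/6)`.

## Synthetic cohorts

No public cohort exists for this analysis, so `population_synthesis`
emulates one.  The only structural assumption is a single latent
per-case disease burden `B ~ LogNormal` on which everything loads:
plaque count `1 + Poisson(1.6·B)`, plaque volume `B · LogNormal`,
calcification count `Poisson(0.021·V_p)` (calcium arises in larger,
more mature plaques), calcified volume fraction `Beta(2, 10.5)` split
across calcifications by a Dirichlet.  A shared factor is the minimal
mechanism that makes *all* pairwise case-level correlations positive,
which is the qualitative structure the analysis needs; the default
rates are calibrated once so a default cohort resembles a clinical
population (≈2.6 plaques and ≈3.2 calcifications per case, ≈150 mm³
mean total plaque volume) and are exposed, not asserted.

Plaque volumes are realized as Model-1 or Model-2 parameter sets
(`growth_mix` controls the share of early-stage partial rings) by
isometric scaling of fixed base shapes; profiles come from the closed
forms plus analytic on-surface path lengths (unrolling the outer wall:
`√(Δz² + (πR)²)` for the full ring's diagonal, `√(h² + (Rθ)²)` for the
partial ring), which dominate the corresponding chords by construction.
Calcification profiles use exact ellipsoid volume, the Thomsen surface
approximation (p = 1.6075, < 1.1% error) and half the Ramanujan
perimeter of the principal ellipse as the surface path.  This is what
makes thousand-case cohorts effectively free; meshes are only built when
a case enters the phantom loop.

What the generator does **not** emulate: curved or branching vessel
anatomy (all shells are straight-axis), per-branch placement, realistic
CT physics (beam hardening, motion), or inter-parameter noise beyond
the latent-burden mechanism.  Consequently, passing tests demonstrate
the internal consistency of models, measurement and statistics — not
clinical realism, and not the specific correlation coefficients of any
real cohort.

## Regression layer

Linear fits are OLS with Pearson r, `R² = r²` and the two-sided p of
`t = r√((n−2)/(1−r²))` on n−2 df; no multiple-testing correction is
applied.  Power fits run nonlinear least squares in the *original*
scale, initialized from log–log OLS (whose exponent is also reported);
original-scale `R² = 1 − SSres/SStot` keeps linear and power fits
comparable and is deliberately not floored at zero.  Relationship
classes use strict thresholds: *strong* if `r > 0.8` and `p < 0.05`,
*significant* if `r > 0.5` and `p < 0.05`, else *none*.  The null
calibration of the p-value (type-I error 5% ± 0.6% at n = 20 over
10,000 replicates) and exponent recovery (2/3 ± 0.01 on isometric S–V
data) are asserted in the test suite.

## Pipeline sizes and determinism

A single mandatory seed fans out to per-stage substreams
(`SeedSequence.spawn`), so identical configurations produce identical
artifact checksums and each stage reruns identically in isolation.
Default run sizes — 100-case cohorts, 2–3 objects through the phantom
loop at 256×64×8 mesh resolution — complete in seconds and were chosen
as the smallest sizes at which every tolerance above has comfortable
margin; all are configurable upward.

## Known limitations

* Graph geodesics are upper bounds with 1–2% bias; exact polyhedral
  geodesics (MMP-style) were not needed at the tolerances used.
* Marching-cubes surfaces of binary masks carry a sub-voxel bias that
  makes the ≥6-voxel wall rule necessary; a signed-distance rasterizer
  would relax it.
* `Model1Params` in non-strict mode describes a formal parameter point,
  not a realizable solid; only closed-form evaluation accepts it.
* The cohort generator's correlations are structural (all positive),
  not calibrated to reproduce any specific cohort's r values.
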