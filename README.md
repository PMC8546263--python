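# plaquegeom

Multidimensional geometry of coronary atherosclerotic plaques: idealized
shell models with closed-form geometry, mesh-based morphometry,
HU-threshold extraction from synthetic CT phantoms, synthetic cohort
generation, and allometric (power-law) regression analysis.

## The problem

Across a population, coronary plaques of very different sizes are
geometrically consistent: pairs of their geometric parameters — volume
*V*, surface area *S*, length *L* (longest chord between the proximal
and distal ends), on-surface distance, maximal cross-section area and
diameter — follow power laws *y = c·xᵉ*.  `plaquegeom` is for researchers
who want to study that scaling quantitatively: it models plaques as
portions of a cylindrical shell wrapped around the artery lumen and
derives, measures and fits the exponents *e* that such shells predict.

Two shell models cover the two plaque morphologies:

* **Model 1** (mature, circumferential): a full cylindrical ring with
  external radius *R*, internal radius *r*, height *h*, and end planes
  slanted by dihedral angles *θ₁, θ₂* —
  *V* = πh(R+r)(R−r), *S* = π(R+r)[2h + (R−r)(sec θ₁ + sec θ₂)],
  *S/V* = 2/(R−r) + (sec θ₁ + sec θ₂)/h.
* **Model 2** (early, patchy): a partial ring spanning a circumferential
  angle *θ* — *V* = (θ/2)h(R+r)(R−r),
  *S/V* = 2[2/(θ(R+r)) + 1/h + 1/(R−r)],
  chord *L* = √(h² + (2R sin(θ/2))²).

Growth hypotheses (isometric scaling; slant growth with secants ∝ scale;
circumferential closure θ → 2π) give limiting log–log slopes
ln *S*/ln *V* → 2/3, 1, 2/3 and ln *L*/ln *V* → 1/3, 2/3, 1/3 — a bracket
that population-fitted exponents (0.741 for S–V, 0.414 for L–V) fall
inside, close to the lower bounds.  See `docs/methods.md` for
derivations, estimators and numerical choices.

## Worked example

```python
from plaquegeom import (
    Model1Params, GrowthHypothesis, model1_metrics, asymptotic_exponent,
    mesh_from_model1, MeshResolution, measure_profile, model_centerline,
)

p = Model1Params(R=2.0, r=1.0, h=10.0, theta1=0.3, theta2=0.2)
m = model1_metrics(p)
print(f"closed form:  V = {m.V:.3f} mm^3   S = {m.S:.3f} mm^2   S/V = {m.sv_ratio:.4f} /mm")

mesh = mesh_from_model1(p, MeshResolution(256, 64, 8))
prof = measure_profile(mesh, model_centerline(p), n_stations=15)
print(f"mesh:         V = {prof.volume:.3f} mm^3   S = {prof.surface_area:.3f} mm^2")
print(f"length = {prof.length:.3f} mm   surface distance = {prof.surface_distance:.3f} mm")
print(f"max cross-section = {prof.cross_section_area:.3f} mm^2   diameter = {prof.cross_section_diameter:.3f} mm")

e = asymptotic_exponent(GrowthHypothesis("H1_1", p), "S_V", k_max=1e4)
print(f"isometric S-V exponent = {e:.6f}   (limit 2/3)")
```

prints

```
closed form:  V = 94.248 mm^3   S = 207.977 mm^2   S/V = 2.2067 /mm
mesh:         V = 94.238 mm^3   S = 207.971 mm^2
length = 11.109 mm   surface distance = 11.276 mm
max cross-section = 9.424 mm^2   diameter = 4.000 mm
isometric S-V exponent = 0.666667   (limit 2/3)
```

The discrete mesh reproduces the closed-form volume and area to 0.01%;
the on-surface distance dominates the straight-line length (the path
must bend around the shell); the maximal cross-section is the annulus
π(R²−r²) ≈ 9.425 mm² with diameter 2R; and the numerically estimated
power-law exponent under isometric growth equals the derived limit 2/3.

The same machinery runs end to end from a shell: `run_pipeline`
synthesizes a cohort, rasterizes selected plaques into HU phantoms,
re-extracts them with the two-step threshold procedure (calcified
>150–1334 HU first, non-calcified 0–150 HU second), surfaces the
components with marching cubes, measures them, and fits linear and
power models at case, plaque and calcification level.

## Command line

```sh
plaquegeom model eval --params params.csv --hypothesis 1.1   # closed forms + exponents
plaquegeom synth mesh --params params.csv --out shell.stl    # STL/PLY generation
plaquegeom synth cohort --n-cases 100 --seed 1 --out cohort/ # synthetic population
plaquegeom measure --mesh shell.stl --centerline line.csv    # morphometry
plaquegeom phantom extract --hu phantom.nii.gz --out comps.csv
plaquegeom stats --level plaque --in table.csv --x volume_mm3 --y surface_area_mm2
plaquegeom run --out run/ --seed 1                           # full pipeline
plaquegeom verify                                            # model verification suite
```

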