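# footmorph

Subject-specific foot modelling from 3D surface scans, for biomechanics
researchers and orthotists who need a finite-element-ready foot model
without MRI or CT imaging.

A subject's foot is scanned (surface only), and a template foot — outer
surface plus a merged internal bone — is morphed onto that scan. The
morphed bone and the scanned skin then define the geometry of a plantar
pressure FE model whose predictions can be validated region by region
against pressure-plate measurements.

## The morphing model

Sixteen named anatomical landmarks (posterior calcaneus … fifth toe tip)
establish correspondence between template and target. Morphing proceeds in
up to three stages:

1. **Affine registration** — the least-squares homogeneous transform `M`
   with `P' = M P` over the landmark pairs (scaling, rotation, shear,
   translation).
2. **RBFPT** (point-based) — a radial-basis-function interpolant fitted on
   the landmark pairs,

   `f(x) = x + Σⱼ cⱼ Φ(‖x − xⱼ‖) + affine tail`,

   which lands every template landmark exactly on its target.
3. **RBFST** (surface-based) — a second RBF fitted on `n` sampled
   correspondences (scaled-surface vertices paired with their closest
   points on the target surface), tightening the fit between landmarks.

Kernels: multiquadric `Φ(r) = √(r² + β)` (MUL, β = 0.2), thin-plate
`Φ(r) = r² log r` (THI), triharmonic `Φ(r) = r³` (TRI).

Morph quality is quantified as a per-vertex **signed geometric error**: the
distance from each scaled-surface vertex to the target surface, negative
when inside (sign by angle-weighted pseudo-normal), summarised as
positive/negative means and extremes.

The FE specification assembles linear-elastic bone (E = 10 GPa, ν = 0.34),
second-order polynomial hyperelastic bulk soft tissue, first-order Ogden
skin (μ = 0.122 MPa, α = 18, 2 mm membrane), foot–plate contact with
friction 0.6, a vertical plate load of half the body weight and an Achilles
pull of a quarter of the body weight, and writes a deterministic
Abaqus-INP-dialect deck. Solving is external.

## Worked example

```python
import numpy as np
import footmorph as fm

# synthetic template (250 mm foot-like surface + bone core + 16 landmarks)
template = fm.make_template(fm.FixtureSpec())

# a known smooth deformation stands in for a subject's scan
field = fm.DeformationField(
    affine=fm.AffineTransform(np.diag([1.06, 1.03, 0.97, 1.0])),
    bumps=(((10.0, -20.0, 15.0), 40.0, (0.0, 0.0, 5.0)),))  # 5 mm arch bump
target, _ = fm.deform(template, field)

cfg = fm.MorphConfig(kernel=fm.RBFKernel("THI"), n_sample_points=500, seed=0)
result = fm.run_pipeline(cfg, template, target.surface, target.landmarks)
stats = fm.summarize(fm.error_map(result.morphed_surface, target.surface))
print(f"mean error +{stats.mean_positive:.4f} / {stats.mean_negative:.4f} mm")
print(f"max  error +{stats.max_positive:.4f} / {stats.max_negative:.4f} mm")
```

Output:

```
mean error +0.0003 / -0.0031 mm
max  error +0.0216 / -0.0243 mm
```

i.e. after the landmark stage and a 500-point surface refinement the
morphed surface sits within about a micrometre (on average) of the target
it was asked to recover — the positive number is the mean distance of
vertices lying outside the target, the negative one of vertices inside.

The same pipeline is available from the shell:

```bash
footmorph fixtures --out bench --seed 0
footmorph morph --template bench/template_surface.stl \
    --bone bench/template_bone.stl --target bench/target_surface.stl \
    --src-landmarks bench/template_landmarks.csv \
    --tgt-landmarks bench/target_landmarks.csv \
    --kernel THI --n-samples 500 --seed 0 --out morphed
footmorph errormap morphed/morphed_surface.stl bench/target_surface.stl \
    --out-csv errors.csv
footmorph export-inp --body-weight 700 --out model.inp
footmorph regions bench/pressure_map.csv --scheme seven --out peaks.csv
```

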