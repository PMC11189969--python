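# Methods

## Scope and model

The package morphs a template foot geometry (outer surface plus a single
merged bone body) onto a subject's scanned foot surface, quantifies the
geometric fidelity of that morph, assembles the resulting geometry into a
finite-element model specification for plantar pressure prediction, and
provides the regional statistics used to compare predicted with measured
pressures. The FE solve itself, volume (tetrahedral) meshing, and any
imaging I/O are deliberately external: the package's contract ends at a
valid, deterministic input deck and begins again at gridded pressure maps.

Coordinate convention, fixed once for the whole package: right-handed,
millimetres, +z superior (gravity axis), +y anterior (toe direction),
+x medial for a right foot.

## Morphing

**Affine stage.** Landmark correspondence (identical name sequences) is
mandatory. The 4x4 homogeneous matrix is the least-squares minimiser of
Σ‖M·Pₖ − P′ₖ‖²; the design matrix must have rank 4 (at least four
non-coplanar source landmarks), and with exactly four such pairs the fit
is exact.

**RBF interpolant.** Both nonlinear stages fit
f(x) = x + Σⱼ cⱼ Φ(‖x − xⱼ‖) [+ affine tail]. The interpolant acts on
*displacements* rather than absolute positions, with a full degree-1
polynomial tail and the moment side-conditions Σcⱼ = 0, Σcⱼxⱼᵀ = 0 by
default. This choice has three consequences that the tests rely on:
zero displacement data give exactly zero coefficients (identity
transform); exactly affine correspondences are absorbed entirely by the
tail (coefficient norm at solver precision); and the thin-plate kernel —
only conditionally positive definite of order 2 — yields a provably
solvable system. A pure-RBF variant without the tail is available and is
stabilised with a Tikhonov ridge of 1e-10 x mean kernel magnitude.

The linear system is equilibrated before solving: the polynomial block is
scaled to the kernel block's mean magnitude, because r³ kernel values at
foot scale (~10⁶) otherwise swamp the affine columns (~10²) and push the
condition number past what LU factorisation tolerates. Systems whose
equilibrated condition number still exceeds 1e14 are rejected with the
condition number in the error message; duplicate source points (pairwise
distance < 1e-9 mm) are rejected up front.

**Kernels.** Triharmonic r³ and thin-plate r²·log r (with Φ(0) = 0 by
continuity) are parameter-free. The multiquadric is implemented as
√(r² + β) with β = 0.2 interpreted as a squared-mm offset on raw
coordinates; the alternative sign convention √(r² − β) is exposed behind
an explicit opt-in flag that raises on radii below √β, where it has no
real value (in particular at r = 0, so it cannot serve as a default).

**Surface-based stage (RBFST).** Correspondences are scaled-surface
vertices drawn uniformly at random without replacement (seeded generator;
a farthest-point-stratified option exists for guaranteed coverage), each
paired with its *closest point on the target surface* — point-to-surface
rather than vertex-index pairing, since scanned and template meshes are
not index-aligned. The target landmarks are kept in the second-stage
system as zero-displacement constraints by default, so the anatomical
correspondence established by the landmark stage cannot drift; sampled
points that coincide with a landmark (within 1e-8 mm) are dropped before
assembly. Closest-point ties are broken toward the lowest triangle index,
making the whole pipeline bit-reproducible for fixed (inputs, config,
seed).

## Geometric error

The signed distance from a query point to the reference surface is the
exact Euclidean distance to the nearest point on any reference triangle
(vectorised Voronoi-region projection, evaluated exhaustively over all
triangles in memory-bounded chunks — the contract is exactness against a
brute-force oracle, so no spatial-acceleration approximations are used).
The sign comes from the angle-weighted pseudo-normal at the closest-point
feature (face, edge, or vertex): negative when the offset vector opposes
it, i.e. the point lies inside. Pseudo-normals make inside/outside
well defined for open surfaces such as trimmed scans, where watertight
containment is unavailable.

Error maps evaluate every vertex of the scaled surface against the target
as reference. Summaries are vertex-weighted (not area-weighted) and keep
the two signs separate: means over the strictly positive and strictly
negative subsets (zeros belong to neither) plus the extreme value of each
sign.

## Surface I/O and trimming

STL (ASCII and binary), PLY, and OBJ are read through trimesh with
post-processing: STL facet soup is welded on bit-identical coordinates,
and PLY per-vertex `quality` properties are loaded as the scalar channel.
Writing uses ASCII STL and OBJ via trimesh and an in-package
double-precision ASCII PLY writer (the scalar carrier). Round trips
through these writers preserve coordinates to 1e-6 mm; binary STL remains
available but is float32-limited (~1e-5 mm at foot scale) by the format
itself.

Scanned surfaces are trimmed 65 mm above the lowest plantar vertex along
the gravity axis — the lowest vertex being the only geometry-intrinsic
datum available when the scanner frame is unknown. Trimming clips crossing
faces exactly at the plane and never increases surface area; a plane that
does not cut the mesh returns it unchanged with a logged notice.

## Constitutive models

Units are N·mm⁻² (≡ MPa) and mm. Bone: linear elastic, E = 10 000 MPa,
ν = 0.34. Bulk soft tissue: second-order polynomial strain energy with
C10 = 0.8556, C01 = −0.0584, C20 = 0.03900, C11 = −0.02319, C02 = 0.00851
N·mm⁻², D1 = 3.65273 mm²·N⁻¹, D2 = 0. A vanishing Dᵢ means the
corresponding volumetric term is *absent* (standard solver convention),
not an infinite stiffness. Skin: first-order Ogden with
U = (2μ/α²)(λ₁^α + λ₂^α + λ₃^α − 3), μ = 0.122 MPa, α = 18, treated as
incompressible — membranes carry no meaningful volumetric stiffness and
no D coefficient exists for the skin. The deck writer emits this form
directly: the Ogden convention used by the target solver dialect is the
same 2μ/α² normalisation, with D = 0 declaring incompressibility.

Deviatoric invariants follow Ī₁ = Σλ̄ᵢ², Ī₂ = Σλ̄ᵢ⁻² with
λ̄ᵢ = J⁻¹ᐟ³λᵢ, so pure dilation leaves both at 3. The uniaxial nominal
stress is the analytic dU/dλ under the incompressible substitution
λ₂ = λ₃ = λ⁻¹ᐟ², verified against central finite differences (h = 1e-6)
to 1e-6 relative away from the stress-free point, where the relative
criterion degenerates and the residual is reported absolutely.

## FE model specification

Element types: C3D4 for bone and bulk, C3D8 for the ground plate, M3D3
membranes for the skin (one per bulk surface triangle, sharing its nodes,
2 mm section thickness, no geometric offset). Loads: plate force =
body_weight/2 applied vertically, Achilles force = body_weight/4 on a
user-supplied attachment node set — the attachment geometry and the fixed
proximal cross-sections are not derivable from a surface scan, so they
are named node sets the caller provides (the synthetic bundle supplies
toy versions). The plate is fixed in all but the vertical direction;
friction coefficient 0.6. Default target element sizes are 3 mm (bone)
and 5 mm (soft tissue, plate); local refinement is represented as
per-region target sizes, not an automatic algorithm. The plate material
(steel-like, E = 210 GPa) is a package choice: it only needs to be rigid
relative to the foot.

The deck writer is byte-deterministic (fixed part order, fixed `%.12g`
float format, full-precision `repr` for per-node load magnitudes so that
load sums reconstruct exactly). The companion reader recovers node and
element counts, section/material assignment, friction, and load sums; it
warns on and skips unknown keywords. The mesh-convergence ladder emits
one spec per (strictly decreasing) element size and records the
acceptance rule — peak-pressure deviation under 5% between successive
refinements — as metadata for the external solver sweep.

## Regional pressure statistics

Pressure maps are uniform grids of cell-centre coordinates (mm) with
nonnegative pressures (kPa). The foot axis defaults to the line from the
pressure-weighted centroid of the posterior 15% band to the centroid of
the anterior 15% band, overridable by explicit heel point / toe
direction. Regions are longitudinal bands by fraction of footprint length
along that axis — heel 0–0.30, midfoot 0.30–0.60, forefoot 0.60–0.85,
toes 0.85–1.0 — with the heel (and, in the eight-region scheme, the
midfoot) split medially/laterally at the axis line, the forefoot split at
medial-to-lateral width fractions 0.40/0.70, and the hallux taking the
medial third of the toe band (remaining toe cells join their forefoot
column). These boundary fractions are a package convention — the region
*names* are standard but no published boundary definition exists — and
every fraction is configurable on the scheme object. Masks are verified
disjoint-and-covering on every call.

Paired comparisons gate on Shapiro–Wilk normality of the paired
differences at α = 0.05 (configurable to per-sample testing): paired
t-test when normality is not rejected, Wilcoxon matched-pairs signed-rank
otherwise — exact p for ≤ 25 nonzero differences, normal approximation
with continuity correction above. All-zero differences return the
degenerate p = 1 on the nonparametric branch. Agreement is Pearson
product-moment correlation plus Bland–Altman mean offset
(predicted − measured) with 95% limits offset ± 1.96·SD. All tests are
two-sided.

## Synthetic fixtures

The template generator maps an icosphere through a smooth injective
parametric function (tapered half-width, ankle-high/toe-low height
profile, power-law sole flattening), producing a watertight foot-like
surface of configurable length (default 250 mm); the bone core is the
same surface scaled toward its centroid (factor 0.6, strictly interior);
the 16 landmarks are placed through the same parametric map, so their
stations are independent of mesh resolution. Ground-truth deformations
combine an affine part with Gaussian radial bumps d·exp(−(‖x−c‖/r)²)
whose magnitudes are capped at r/2, keeping the field a diffeomorphism.
Pressure maps are two Gaussian lobes (heel-dominant by default,
121/107 kPa) with seeded noise bounded at 2% of the larger peak and lobe
centres snapped to grid nodes so stated peaks are attained exactly.

The benchmark configuration (250 mm fixture, 1.06/1.03/0.97 anisotropic
affine plus one 5 mm arch bump of 40 mm radius) exercises exactly what
the morphing pipeline claims to recover: a smooth, invertible,
subject-like shape change. What it does not emulate: scanner noise and
holes, toe-posture differences between template and subject, landmark
placement error, or anatomical bone detail — so passing the benchmark
demonstrates correctness of the transformations, not clinical accuracy on
real scans. Benchmark meshes use 2562 surface vertices (icosphere
subdivision 4), enough to support 1000-point surface sampling while
keeping a full variant sweep under a minute; unit tests use the 642-vertex
fixture.

## Numerical choices and limitations

* Exactness tolerances: RBF source residuals < 1e-6 mm; identity
  pipelines < 1e-8 mm; signed distance vs brute force < 1e-9 mm.
* Closest-point and argmin ties resolve to the lowest index;
  random sampling uses numpy's PCG64 generator, seeded everywhere.
* Degenerate inputs fail loudly: empty meshes, coplanar landmark sets,
  duplicate source points, all-zero-area references, non-manifold skin
  surfaces, non-positive stretches, empty footprints.
* The error summaries are vertex statistics; meshes with strongly
  nonuniform triangle areas weight dense regions more heavily.
* The pipeline preserves template topology by construction and never
  checks for self-intersection of the morphed surface; extreme target
  deformations outside the generator's invertibility bound can fold it.
* Peak extraction reports the single maximum cell per region; no
  sensor-style spatial averaging is applied.
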