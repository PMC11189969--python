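"""Landmark- and surface-driven template morphing.

A template foot (outer surface plus merged internal bone) is warped onto a
subject's scanned surface in up to three stages:

1. **Affine registration** — the least-squares 4x4 homogeneous transform
   mapping the 16 template landmarks onto the subject's landmarks
   (scaling, rotation, shear, translation).
2. **RBFPT** — a radial-basis-function interpolant fitted on the landmark
   pairs (point-based transformation), warping the affinely scaled
   template so every landmark lands exactly on its subject counterpart.
3. **RBFST** — an optional second RBF fitted on sampled surface
   correspondences (scaled-surface vertices paired with their closest
   points on the target surface), tightening the fit between landmarks.

The RBF interpolant maps a free point ``x`` through

    f(x) = x + sum_j c_j * Phi(||x - x_j||)  [+ affine tail]

with kernel ``Phi`` one of multiquadric ``sqrt(r^2 + beta)`` (MUL),
thin-plate ``r^2 log r`` (THI), or triharmonic ``r^3`` (TRI).  The
displacement (rather than absolute-position) formulation plus an affine
polynomial tail makes the interpolant exactly reproduce affine motions and
behave as the identity far from the data when there is nothing to correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .error_analysis import closest_points
from .mesh_io import LandmarkSet, TriangleSurfaceMesh

__all__ = [
    "AffineTransform",
    "RBFKernel",
    "RBFTransform",
    "MorphConfig",
    "MorphResult",
    "TemplateBundle",
    "fit_affine",
    "kernel_eval",
    "fit_rbf",
    "apply_rbf",
    "morph_rbfpt",
    "sample_correspondences",
    "morph_rbfst",
    "run_pipeline",
]

KERNEL_FAMILIES = ("MUL", "THI", "TRI")
METHODS = ("RBFPT", "RBFPT+RBFST")


@dataclass(frozen=True)
class AffineTransform:
    """Homogeneous 4x4 affine transform (mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("bottom row of affine matrix must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) <= 1e-12:
            raise ValueError("affine linear block is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]


@dataclass(frozen=True)
class RBFKernel:
    """Radial kernel family with optional multiquadric shape parameter.

    ``beta`` (mm^2 offset under the square root) only applies to MUL; the
    default 0.2 follows common practice for foot-scale geometry.  The
    multiquadric is implemented with the well-posed ``sqrt(r^2 + beta)``
    form; ``printed_form=True`` opts into ``sqrt(r^2 - beta)``, which is
    imaginary for r < sqrt(beta) and therefore raises on such radii.
    """

    family: str = "THI"
    beta: float = 0.2
    printed_form: bool = False

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"kernel family must be one of {KERNEL_FAMILIES}")
        if self.family == "MUL" and not self.beta > 0:
            raise ValueError("MUL kernel requires beta > 0")


def kernel_eval(kernel: RBFKernel, r) -> np.ndarray:
    """Evaluate the radial kernel at radii ``r`` (mm, >= 0)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    if kernel.family == "TRI":
        return r ** 3
    if kernel.family == "THI":
        out = np.zeros_like(r)
        mask = r > 0
        rm = r[mask] if r.ndim else r
        if r.ndim:
            out[mask] = rm * rm * np.log(rm)
        elif r > 0:
            out = r * r * np.log(r)
        return out
    if kernel.printed_form:
        arg = r * r - kernel.beta
        if np.any(arg < 0):
            raise ValueError(
                "printed multiquadric sqrt(r^2 - beta) is imaginary for "
                f"r < sqrt(beta) = {np.sqrt(kernel.beta):.4g}")
        return np.sqrt(arg)
    return np.sqrt(r * r + kernel.beta)


@dataclass(frozen=True)
class RBFTransform:
    """Fitted RBF displacement interpolant.

    ``coefficients`` is (n, 3): one displacement coefficient row per source
    point.  ``affine_tail`` is an optional (4, 3) polynomial part acting on
    homogeneous coordinates (1, x, y, z); when present the coefficients
    satisfy the moment conditions sum_j c_j = 0 and sum_j c_j x_j^T = 0.
    """

    kernel: RBFKernel
    sources: np.ndarray
    coefficients: np.ndarray
    affine_tail: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        src = np.asarray(self.sources, dtype=np.float64).reshape(-1, 3)
        coef = np.asarray(self.coefficients, dtype=np.float64).reshape(-1, 3)
        if len(src) != len(coef):
            raise ValueError("coefficient rows must match source count")
        object.__setattr__(self, "sources", src)
        object.__setattr__(self, "coefficients", coef)
        if self.affine_tail is not None:
            tail = np.asarray(self.affine_tail, dtype=np.float64)
            if tail.shape != (4, 3):
                raise ValueError("affine tail must be 4x3")
            object.__setattr__(self, "affine_tail", tail)
            scale = max(1.0, np.abs(coef).max(initial=0.0))
            if np.abs(coef.sum(axis=0)).max() > 1e-8 * scale * max(1, len(src)):
                raise ValueError("moment condition sum c_j = 0 violated")
            moment = coef.T @ src
            pscale = max(1.0, np.abs(src).max()) * scale * max(1, len(src))
            if np.abs(moment).max() > 1e-8 * pscale:
                raise ValueError("moment condition sum c_j x_j^T = 0 violated")

    @property
    def n_sources(self) -> int:
        return len(self.sources)


def fit_affine(source, target) -> AffineTransform:
    """Least-squares affine transform mapping source landmarks to targets.

    Accepts :class:`LandmarkSet` pairs (which must correspond: identical
    name sequences) or bare (n, 3) arrays.  Requires at least 4
    non-coplanar source points; with exactly 4 such points the fit is
    exact.
    """
    if isinstance(source, LandmarkSet) or isinstance(target, LandmarkSet):
        if not (isinstance(source, LandmarkSet) and isinstance(target, LandmarkSet)):
            raise ValueError("source and target must both be LandmarkSets or both arrays")
        if not source.corresponds_to(target):
            raise ValueError("landmark sets do not correspond (names/order differ)")
        src, tgt = source.points, target.points
    else:
        src = np.asarray(source, dtype=np.float64).reshape(-1, 3)
        tgt = np.asarray(target, dtype=np.float64).reshape(-1, 3)
    if len(src) != len(tgt):
        raise ValueError("source/target point counts differ")
    if len(src) < 4:
        raise ValueError("affine fit needs at least 4 point pairs")
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) < 4:
        raise ValueError("rank-deficient affine fit: source points are coplanar")
    sol, *_ = np.linalg.lstsq(design, tgt, rcond=None)
    m = np.eye(4)
    m[:3, :3] = sol[:3].T
    m[:3, 3] = sol[3]
    return AffineTransform(m)


def _check_distinct(points: np.ndarray) -> None:
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(f"duplicate source points at indices {i} and {j}")


def fit_rbf(sources, targets, kernel: RBFKernel,
            with_affine_tail: bool = True,
            regularization: Optional[float] = None) -> RBFTransform:
    """Fit an RBF displacement interpolant mapping sources onto targets.

    With the affine tail (default) the kernel system is augmented with a
    full degree-1 polynomial and the moment side-conditions, which makes
    the system well posed for all three kernels (thin-plate is only
    conditionally positive definite of order 2) and lets an exactly affine
    correspondence be absorbed entirely by the tail.  Without the tail a
    small Tikhonov ridge (1e-10 of the mean kernel magnitude unless given)
    stabilises the pure-RBF solve.
    """
    src = np.asarray(sources, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(targets, dtype=np.float64).reshape(-1, 3)
    if len(src) != len(tgt):
        raise ValueError("source/target point counts differ")
    n = len(src)
    if n < 4:
        raise ValueError("RBF fit needs at least 4 point pairs")
    _check_distinct(src)
    disp = tgt - src
    kmat = kernel_eval(kernel, cdist(src, src))
    if with_affine_tail:
        # equilibrate: scale the polynomial block to the kernel block's
        # magnitude (r^3 at foot scale dwarfs the affine columns otherwise)
        scale = max(float(np.abs(kmat).mean()), 1.0)
        p = np.hstack([np.ones((n, 1)), src]) * scale
        a = np.zeros((n + 4, n + 4))
        a[:n, :n] = kmat
        a[:n, n:] = p
        a[n:, :n] = p.T
        rhs = np.vstack([disp, np.zeros((4, 3))])
    else:
        lam = regularization
        if lam is None:
            lam = 1e-10 * float(np.abs(kmat).mean())
        a = kmat + lam * np.eye(n)
        rhs = disp
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"RBF system is numerically singular (condition number {cond:.3g})")
    sol = np.linalg.solve(a, rhs)
    if with_affine_tail:
        return RBFTransform(kernel, src, sol[:n], sol[n:] * scale)
    return RBFTransform(kernel, src, sol, None)


def apply_rbf(transform: RBFTransform, points) -> np.ndarray:
    """Evaluate the fitted interpolant at arbitrary points."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    phi = kernel_eval(transform.kernel, cdist(p, transform.sources))
    out = p + phi @ transform.coefficients
    if transform.affine_tail is not None:
        out = out + np.hstack([np.ones((len(p), 1)), p]) @ transform.affine_tail
    return out


def _source_residual(transform: RBFTransform, targets: np.ndarray) -> float:
    mapped = apply_rbf(transform, transform.sources)
    return float(np.linalg.norm(mapped - targets, axis=1).max())


# ---------------------------------------------------------------------------
# pipeline types

@dataclass(frozen=True)
class MorphConfig:
    """Configuration of the morphing pipeline.

    ``method`` selects landmark-only morphing (``"RBFPT"``) or the full
    two-stage procedure (``"RBFPT+RBFST"``).  ``n_sample_points`` controls
    the RBFST surface-correspondence density (common choices: 100, 500,
    1000, 1500); ``keep_landmarks_in_rbfst`` pins the anatomical landmarks
    as zero-displacement constraints in the second stage.
    """

    method: str = "RBFPT+RBFST"
    kernel: RBFKernel = field(default_factory=RBFKernel)
    n_sample_points: int = 1000
    seed: int = 0
    keep_landmarks_in_rbfst: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.n_sample_points < 4:
            raise ValueError("n_sample_points must be at least 4")


@dataclass(frozen=True)
class TemplateBundle:
    """Template geometry: outer surface, merged bone, and its landmarks."""

    surface: TriangleSurfaceMesh
    bone: TriangleSurfaceMesh
    landmarks: LandmarkSet


@dataclass
class MorphResult:
    """Morphed geometry plus the transforms and provenance that made it."""

    morphed_surface: TriangleSurfaceMesh
    morphed_bone: TriangleSurfaceMesh
    affine: AffineTransform
    rbf_stages: list
    provenance: dict

    def provenance_json(self) -> str:
        """Structured text sidecar describing the run."""
        return json.dumps(self.provenance, indent=2, sort_keys=True)


def _kernel_meta(kernel: RBFKernel) -> dict:
    meta = {"family": kernel.family}
    if kernel.family == "MUL":
        meta["beta"] = kernel.beta
        meta["printed_form"] = kernel.printed_form
    return meta


def morph_rbfpt(template_surface: TriangleSurfaceMesh,
                template_bone: TriangleSurfaceMesh,
                src_landmarks: LandmarkSet,
                tgt_landmarks: LandmarkSet,
                kernel: RBFKernel = RBFKernel()) -> MorphResult:
    """Landmark-driven morph: affine registration followed by an RBF warp.

    The affine stage is fitted on the landmark pairs and applied to the
    surface, bone and source landmarks; the RBF stage then interpolates the
    residual landmark displacements, so every source landmark lands exactly
    on its target.  Mesh topology is untouched.
    """
    if not src_landmarks.corresponds_to(tgt_landmarks):
        raise ValueError("landmark sets do not correspond (names/order differ)")
    affine = fit_affine(src_landmarks, tgt_landmarks)
    surf_v = affine.apply(template_surface.vertices)
    bone_v = affine.apply(template_bone.vertices)
    lm_v = affine.apply(src_landmarks.points)
    rbf = fit_rbf(lm_v, tgt_landmarks.points, kernel)
    surface = template_surface.with_vertices(apply_rbf(rbf, surf_v))
    bone = template_bone.with_vertices(apply_rbf(rbf, bone_v))
    residual = _source_residual(rbf, tgt_landmarks.points)
    provenance = {
        "stages": [
            {"stage": "affine",
             "landmark_rms_mm": float(np.sqrt(np.mean(
                 np.sum((lm_v - tgt_landmarks.points) ** 2, axis=1))))},
            {"stage": "RBFPT", "kernel": _kernel_meta(kernel),
             "n_landmarks": len(src_landmarks),
             "max_source_residual_mm": residual},
        ],
        "target_landmarks": tgt_landmarks.points.tolist(),
        "landmark_names": list(tgt_landmarks.names),
    }
    return MorphResult(surface, bone, affine, [rbf], provenance)


def sample_correspondences(scaled_surface: TriangleSurfaceMesh,
                           target_surface: TriangleSurfaceMesh,
                           n: int, seed: int,
                           stratified: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Sample surface correspondences for the RBFST stage.

    ``n`` vertices of the scaled surface are drawn uniformly at random
    without replacement (seeded; ``stratified=True`` instead picks a
    farthest-point subsample for even coverage) and each is paired with its
    closest point on the target surface.
    """
    if n < 4:
        raise ValueError("need at least 4 correspondences")
    nv = scaled_surface.n_vertices
    if n > nv:
        raise ValueError(f"requested {n} samples but surface has {nv} vertices")
    rng = np.random.default_rng(seed)
    if stratified:
        start = int(rng.integers(nv))
        chosen = [start]
        d = np.linalg.norm(scaled_surface.vertices - scaled_surface.vertices[start], axis=1)
        for _ in range(n - 1):
            nxt = int(np.argmax(d))
            chosen.append(nxt)
            d = np.minimum(d, np.linalg.norm(
                scaled_surface.vertices - scaled_surface.vertices[nxt], axis=1))
        idx = np.array(chosen)
    else:
        idx = rng.choice(nv, size=n, replace=False)
    sources = scaled_surface.vertices[idx]
    targets, _, _ = closest_points(sources, target_surface)
    return sources, targets


def morph_rbfst(rbfpt_result: MorphResult,
                target_surface: TriangleSurfaceMesh,
                kernel: RBFKernel = RBFKernel(),
                n_sample_points: int = 1000,
                seed: int = 0,
                keep_landmarks: bool = True,
                template_bundle: Optional[TemplateBundle] = None) -> MorphResult:
    """Surface-correspondence refinement of an RBFPT result.

    A second RBF is fitted on sampled vertex-to-closest-point pairs between
    the RBFPT-scaled surface and the target; when ``keep_landmarks`` the
    target landmarks are added as zero-displacement constraints so the
    anatomical correspondence from the first stage never drifts.
    """
    sources, targets = sample_correspondences(
        rbfpt_result.morphed_surface, target_surface, n_sample_points, seed)
    if keep_landmarks:
        lm = np.asarray(rbfpt_result.provenance.get("target_landmarks", []), dtype=np.float64)
        if lm.size:
            keep = np.ones(len(sources), dtype=bool)
            for p in lm.reshape(-1, 3):
                keep &= np.linalg.norm(sources - p, axis=1) > 1e-8
            sources = np.vstack([lm.reshape(-1, 3), sources[keep]])
            targets = np.vstack([lm.reshape(-1, 3), targets[keep]])
    rbf = fit_rbf(sources, targets, kernel)
    surface = rbfpt_result.morphed_surface.with_vertices(
        apply_rbf(rbf, rbfpt_result.morphed_surface.vertices))
    bone = rbfpt_result.morphed_bone.with_vertices(
        apply_rbf(rbf, rbfpt_result.morphed_bone.vertices))
    provenance = dict(rbfpt_result.provenance)
    provenance["stages"] = list(provenance["stages"]) + [{
        "stage": "RBFST", "kernel": _kernel_meta(kernel),
        "n_sample_points": int(n_sample_points),
        "n_constraints": int(len(sources)),
        "seed": int(seed),
        "keep_landmarks": bool(keep_landmarks),
        "max_source_residual_mm": _source_residual(rbf, targets),
    }]
    return MorphResult(surface, bone, rbfpt_result.affine,
                       list(rbfpt_result.rbf_stages) + [rbf], provenance)


def run_pipeline(config: MorphConfig,
                 template: TemplateBundle,
                 target_surface: TriangleSurfaceMesh,
                 target_landmarks: LandmarkSet) -> MorphResult:
    """Run the configured morphing pipeline template -> target.

    Dispatches among the four study variants: RBFPT alone, or RBFPT
    followed by RBFST with the THI / MUL / TRI kernel.  Every stage and its
    residual is recorded in the result provenance; fixed (config, inputs)
    give a bit-reproducible result.
    """
    result = morph_rbfpt(template.surface, template.bone,
                         template.landmarks, target_landmarks, config.kernel)
    if config.method == "RBFPT+RBFST":
        result = morph_rbfst(result, target_surface, config.kernel,
                             config.n_sample_points, config.seed,
                             config.keep_landmarks_in_rbfst)
    result.provenance["config"] = {
        "method": config.method,
        "kernel": _kernel_meta(config.kernel),
        "n_sample_points": config.n_sample_points,
        "seed": config.seed,
        "keep_landmarks_in_rbfst": config.keep_landmarks_in_rbfst,
    }
    return result
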