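"""Signed geometric error between a scaled surface and a target surface.

The geometric error of a morph is evaluated per vertex of the scaled
surface: the magnitude is the exact Euclidean distance to the closest point
anywhere on the reference (target) triangulation, and the sign follows the
angle-weighted pseudo-normal at that closest point — negative when the
vertex lies inside the reference, positive outside.  Pseudo-normals give a
well-defined inside/outside even for open (trimmed) surfaces, where
watertight containment is meaningless.

Summaries follow the convention of reporting positive and negative errors
separately: means over the strictly positive / strictly negative subsets
and the extreme values of each sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_io import TriangleSurfaceMesh

__all__ = [
    "ErrorMap",
    "ErrorStats",
    "closest_points",
    "signed_distance",
    "error_map",
    "summarize",
]


# ---------------------------------------------------------------------------
# exact point-to-triangle projection, vectorised over (points x triangles)

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    p: (k, 3); tri: (m, 3, 3).  Returns (k, m, 3) closest points.
    Branchless region classification (Voronoi regions of the triangle).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]            # (m,3)
    ab = b - a
    ac = c - a
    pa = p[:, None, :] - a[None, :, :]                   # (k,m,3)
    d1 = np.einsum("mi,kmi->km", ab, pa)
    d2 = np.einsum("mi,kmi->km", ac, pa)
    pb = p[:, None, :] - b[None, :, :]
    d3 = np.einsum("mi,kmi->km", ab, pb)
    d4 = np.einsum("mi,kmi->km", ac, pb)
    pc = p[:, None, :] - c[None, :, :]
    d5 = np.einsum("mi,kmi->km", ab, pc)
    d6 = np.einsum("mi,kmi->km", ac, pc)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    out = a[None, :, :] + v_in[..., None] * ab[None, :, :] + w_in[..., None] * ac[None, :, :]

    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    cand = b[None, :, :] + np.clip(np.nan_to_num(w_bc), 0, 1)[..., None] * (c - b)[None, :, :]
    out = np.where(m_bc[..., None], cand, out)

    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cand = a[None, :, :] + np.clip(np.nan_to_num(w_ac), 0, 1)[..., None] * ac[None, :, :]
    out = np.where(m_ac[..., None], cand, out)

    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cand = a[None, :, :] + np.clip(np.nan_to_num(v_ab), 0, 1)[..., None] * ab[None, :, :]
    out = np.where(m_ab[..., None], cand, out)

    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], np.broadcast_to(c[None, :, :], out.shape), out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], np.broadcast_to(b[None, :, :], out.shape), out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], np.broadcast_to(a[None, :, :], out.shape), out)
    return out


def closest_points(points, reference: TriangleSurfaceMesh,
                   chunk: int = 128) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest point on ``reference`` for every query point.

    Exact minimisation over all triangles (evaluated in chunks to bound
    memory); ties broken toward the lowest triangle index.  Returns
    ``(closest (n,3), distance (n,), triangle_index (n,))``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not np.all(np.isfinite(pts)):
        raise ValueError("query points must be finite")
    if reference.n_faces == 0:
        raise ValueError("reference surface has no faces")
    tri = reference.triangles()
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    if np.all(areas <= 0):
        raise ValueError("degenerate reference: all triangles have zero area")
    n = len(pts)
    closest = np.empty((n, 3))
    dist = np.empty(n)
    tri_idx = np.empty(n, dtype=np.int64)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        cp = _closest_on_triangles(pts[sl], tri)             # (k,m,3)
        d2 = np.einsum("kmi,kmi->km", cp - pts[sl][:, None, :], cp - pts[sl][:, None, :])
        j = np.argmin(d2, axis=1)                            # first minimum: lowest index
        rows = np.arange(len(j))
        closest[sl] = cp[rows, j]
        dist[sl] = np.sqrt(d2[rows, j])
        tri_idx[sl] = j
    return closest, dist, tri_idx


# ---------------------------------------------------------------------------
# pseudo-normals

def _pseudo_normals(mesh: TriangleSurfaceMesh):
    """Face normals, angle-weighted vertex normals, and edge normals.

    Edge normals are the (normalised) sum of the normals of the faces
    sharing the edge; vertex normals weight each incident face normal by
    the interior angle at the vertex.
    """
    tri = mesh.triangles()
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    fn = fn / norms

    vn = np.zeros_like(mesh.vertices)
    for corner in range(3):
        e1 = tri[:, (corner + 1) % 3] - tri[:, corner]
        e2 = tri[:, (corner + 2) % 3] - tri[:, corner]
        cosang = np.einsum("ij,ij->i", e1, e2) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1))
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(vn, mesh.faces[:, corner], fn * ang[:, None])
    vnorm = np.linalg.norm(vn, axis=1, keepdims=True)
    vnorm[vnorm == 0] = 1.0
    vn = vn / vnorm

    en: dict[tuple[int, int], np.ndarray] = {}
    for f, face in enumerate(mesh.faces):
        for i in range(3):
            key = tuple(sorted((int(face[i]), int(face[(i + 1) % 3]))))
            en[key] = en.get(key, 0.0) + fn[f]
    for key, vec in en.items():
        nn = np.linalg.norm(vec)
        en[key] = vec / nn if nn > 0 else vec
    return fn, vn, en


def _barycentric(point: np.ndarray, tri: np.ndarray) -> np.ndarray:
    v0, v1 = tri[1] - tri[0], tri[2] - tri[0]
    v2 = point - tri[0]
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    denom = d00 * d11 - d01 * d01
    if denom == 0:
        return np.array([1.0, 0.0, 0.0])
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.array([1.0 - v - w, v, w])


def signed_distance(points, reference: TriangleSurfaceMesh) -> np.ndarray:
    """Signed distance from each point to ``reference`` (mm).

    Magnitude is the exact distance to the closest point on any reference
    triangle; the sign is negative when the offset vector opposes the
    angle-weighted pseudo-normal at the closest point (point inside the
    reference surface), positive otherwise.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    cp, dist, tri_idx = closest_points(pts, reference)
    fn, vn, en = _pseudo_normals(reference)
    tri = reference.triangles()

    signs = np.ones(len(pts))
    eps = 1e-9
    for i in range(len(pts)):
        if dist[i] <= eps:
            continue
        f = tri_idx[i]
        bary = _barycentric(cp[i], tri[f])
        scale = max(1.0, np.abs(bary).max())
        on = bary > eps * scale
        face = reference.faces[f]
        if on.sum() == 3:
            normal = fn[f]
        elif on.sum() == 2:
            ij = face[on]
            normal = en[tuple(sorted((int(ij[0]), int(ij[1]))))]
        else:
            normal = vn[face[int(np.argmax(bary))]]
        if (pts[i] - cp[i]) @ normal < 0:
            signs[i] = -1.0
    return signs * dist


# ---------------------------------------------------------------------------
# error maps and summaries

@dataclass
class ErrorMap:
    """Per-vertex signed distance (mm) of a scaled surface to a reference."""

    mesh: TriangleSurfaceMesh
    signed_distance: np.ndarray

    def __post_init__(self) -> None:
        self.signed_distance = np.asarray(self.signed_distance, dtype=np.float64).ravel()
        if self.signed_distance.shape != (self.mesh.n_vertices,):
            raise ValueError("one signed distance per vertex required")
        if not np.all(np.isfinite(self.signed_distance)):
            raise ValueError("non-finite signed distance")

    def as_mesh(self) -> TriangleSurfaceMesh:
        """The evaluated mesh with the error map attached as scalar channel."""
        return TriangleSurfaceMesh(self.mesh.vertices.copy(), self.mesh.faces.copy(),
                                   self.signed_distance.copy())


@dataclass(frozen=True)
class ErrorStats:
    """Positive/negative mean and extreme signed distances (mm)."""

    mean_positive: float
    mean_negative: float
    max_positive: float
    max_negative: float
    n_positive: int
    n_negative: int
    n_zero: int

    @property
    def mean_abs(self) -> float:
        n = self.n_positive + self.n_negative + self.n_zero
        if n == 0:
            return 0.0
        return (self.mean_positive * self.n_positive
                - self.mean_negative * self.n_negative) / n

    def to_row(self) -> dict:
        return {
            "mean_positive_mm": self.mean_positive,
            "mean_negative_mm": self.mean_negative,
            "max_positive_mm": self.max_positive,
            "max_negative_mm": self.max_negative,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_zero": self.n_zero,
        }


def error_map(scaled: TriangleSurfaceMesh, target: TriangleSurfaceMesh) -> ErrorMap:
    """Signed distance of every vertex of ``scaled`` to the ``target`` surface.

    The target (scanned) surface is the reference: negative values mean the
    scaled surface lies inside it.
    """
    return ErrorMap(scaled, signed_distance(scaled.vertices, target))


def summarize(emap: ErrorMap) -> ErrorStats:
    """Positive/negative means and extremes of an error map."""
    d = emap.signed_distance
    if d.size == 0:
        raise ValueError("empty error map")
    pos = d[d > 0]
    neg = d[d < 0]
    return ErrorStats(
        mean_positive=float(pos.mean()) if pos.size else 0.0,
        mean_negative=float(neg.mean()) if neg.size else 0.0,
        max_positive=float(d.max()) if d.max() > 0 else 0.0,
        max_negative=float(d.min()) if d.min() < 0 else 0.0,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        n_zero=int(d.size - pos.size - neg.size),
    )
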