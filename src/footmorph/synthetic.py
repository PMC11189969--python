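"""Synthetic foot fixtures: geometry, deformation fields, pressure maps.

Everything the package needs for hermetic testing and benchmarking is
generated here programmatically:

* a parametric foot-like closed surface (a smoothly remapped icosphere:
  tapered heel, wider forefoot, lowered toe profile, flattened sole) with
  an embedded bone core and the canonical 16 named landmarks placed by
  parametric position (stable across mesh resolutions);
* smooth ground-truth deformation fields (an affine part plus Gaussian
  radial bumps) whose exact per-vertex displacements are known, used to
  score morph recovery;
* two-lobed plantar pressure maps (heel- and forefoot-dominant Gaussian
  lobes plus bounded noise).

Every generator is deterministic under its seed.  The fixtures emulate the
geometric character of scanned feet — scale, closedness, landmarks, smooth
subject-to-subject deformation — not anatomical detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh
from scipy.spatial.distance import pdist

from .mesh_io import FOOT_LANDMARK_NAMES, LandmarkSet, TriangleSurfaceMesh
from .morphing import AffineTransform, TemplateBundle
from .region_stats import PressureMap

__all__ = [
    "FixtureSpec",
    "DeformationField",
    "make_template",
    "deform",
    "make_pressure_map",
    "make_volume_parts",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic foot fixture (mm)."""

    length: float = 250.0
    width: float = 95.0
    height: float = 80.0
    bone_scale: float = 0.6
    subdivisions: int = 3       # icosphere refinement; 3 -> 642 vertices
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("fixture dimensions must be positive")
        if not 0 < self.bone_scale < 1:
            raise ValueError("bone core scale must lie in (0, 1)")
        if self.subdivisions < 2:
            raise ValueError("resolution too coarse to carry 16 distinct landmarks")


def _foot_map(spec: FixtureSpec, s: np.ndarray) -> np.ndarray:
    """Map unit-sphere points to the foot-like surface (injective, smooth)."""
    sx, sy, sz = s[:, 0], s[:, 1], s[:, 2]
    # half-width profile: narrow heel, widest near the metatarsal heads
    w = 0.75 + 0.35 * np.exp(-(((sy - 0.4) / 0.55) ** 2))
    # height profile: tall at the ankle, low toward the toes
    h = 0.45 + 0.55 * np.exp(-(((sy + 0.55) / 0.6) ** 2))
    x = 0.5 * spec.width * sx * w
    y = 0.5 * spec.length * sy
    # monotone power law in sz flattens the sole while staying injective
    z = spec.height * ((sz + 1.0) / 2.0) ** 1.4 * h
    return np.column_stack([x, y, z])


# parametric unit-sphere directions of the 16 landmarks, ordered as
# FOOT_LANDMARK_NAMES (+x medial, +y anterior, +z superior; right foot)
_LANDMARK_DIRECTIONS: tuple[tuple[float, float, float], ...] = (
    (0.00, -1.00, -0.20),   # posterior calcaneus
    (0.00, -0.70, -1.00),   # central plantar heel
    (0.80, -0.80, -0.30),   # heel medial
    (-0.80, -0.80, -0.30),  # heel lateral
    (0.00, -0.90, 0.60),    # achilles tendon between malleoli
    (1.00, -0.50, 0.50),    # malleolus medial
    (-1.00, -0.50, 0.50),   # malleolus lateral
    (1.00, -0.10, -0.10),   # navicular tuberosity
    (0.20, -0.15, 1.00),    # navicular dorsal
    (-1.00, 0.10, -0.20),   # fifth metatarsal basis
    (1.00, 0.50, -0.40),    # first metatarsal head
    (0.20, 0.25, 1.00),     # second tarsometatarsal dorsal
    (0.00, 0.55, -1.00),    # third metatarsophalangeal plantar
    (0.55, 1.00, -0.10),    # hallux tip
    (0.15, 1.00, -0.10),    # second toe tip
    (-0.60, 0.95, -0.15),   # fifth toe tip
)


def make_template(spec: FixtureSpec = FixtureSpec()) -> TemplateBundle:
    """Build the synthetic template: surface, inner bone core, 16 landmarks.

    The surface is a watertight foot-like shape; the bone core is the same
    surface scaled toward its centroid by ``bone_scale`` (strictly interior
    for all default parameters).  Landmarks are placed through the same
    parametric map as the surface, so their anatomical stations do not move
    when the mesh resolution changes.
    """
    sphere = trimesh.creation.icosphere(subdivisions=spec.subdivisions)
    verts = _foot_map(spec, np.asarray(sphere.vertices, dtype=np.float64))
    faces = np.asarray(sphere.faces, dtype=np.int64)
    surface = TriangleSurfaceMesh(verts, faces)

    center = verts.mean(axis=0)
    bone = TriangleSurfaceMesh(center + spec.bone_scale * (verts - center), faces.copy())

    dirs = np.asarray(_LANDMARK_DIRECTIONS, dtype=np.float64)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    lm_points = _foot_map(spec, dirs)
    if pdist(lm_points).min() < 1.0:
        raise ValueError("landmark stations collapse at this fixture size")
    landmarks = LandmarkSet(FOOT_LANDMARK_NAMES, lm_points)
    return TemplateBundle(surface, bone, landmarks)


@dataclass(frozen=True)
class DeformationField:
    """Smooth invertible ground-truth deformation: affine + Gaussian bumps.

    Each bump is ``(center (mm), radius (mm), displacement vector (mm))``
    contributing ``d * exp(-(|x - c| / r)^2)``.  Displacement magnitudes
    are capped at radius/2, which keeps the field a diffeomorphism (the
    bump's Lipschitz constant stays below 1).
    """

    affine: AffineTransform = field(default_factory=AffineTransform.identity)
    bumps: tuple = ()

    def __post_init__(self) -> None:
        checked = []
        for center, radius, disp in self.bumps:
            center = np.asarray(center, dtype=np.float64).reshape(3)
            disp = np.asarray(disp, dtype=np.float64).reshape(3)
            radius = float(radius)
            if radius <= 0:
                raise ValueError("bump radius must be positive")
            if np.linalg.norm(disp) >= radius / 2.0:
                raise ValueError(
                    "bump displacement must stay below radius/2 for invertibility")
            checked.append((center, radius, disp))
        object.__setattr__(self, "bumps", tuple(checked))

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = self.affine.apply(p)
        for center, radius, disp in self.bumps:
            g = np.exp(-np.sum(((p - center) / radius) ** 2, axis=1))
            out = out + g[:, None] * disp
        return out


def deform(bundle: TemplateBundle, field: DeformationField
           ) -> tuple[TemplateBundle, np.ndarray]:
    """Apply a ground-truth field to a template bundle.

    Returns the deformed bundle (surface, bone, landmarks all mapped
    through the field) and the exact per-vertex displacement of the
    surface, for recovery scoring.
    """
    surf_v = field.apply(bundle.surface.vertices)
    bone_v = field.apply(bundle.bone.vertices)
    lm_v = field.apply(bundle.landmarks.points)
    deformed = TemplateBundle(
        bundle.surface.with_vertices(surf_v),
        bundle.bone.with_vertices(bone_v),
        LandmarkSet(bundle.landmarks.names, lm_v),
    )
    return deformed, surf_v - bundle.surface.vertices


def make_pressure_map(length: float = 250.0,
                      peak_heel: float = 121.0,
                      peak_forefoot: float = 107.0,
                      seed: int = 0,
                      spacing: float = 5.0,
                      noise: float = 0.02,
                      side: str = "right") -> PressureMap:
    """Two-lobed synthetic plantar pressure map (kPa).

    Gaussian lobes at the heel and forefoot (hallux-side bias in the
    forefoot lobe); the default peaks of 121/107 kPa reproduce the
    heel-dominant pattern typical of balanced standing.  Seeded uniform
    noise bounded by ``noise`` (fraction of the larger peak) is added on
    loaded cells; lobe centres snap to grid nodes so the stated peaks are
    attained exactly when ``noise=0``.
    """
    if peak_heel <= 0 or peak_forefoot <= 0:
        raise ValueError("peak pressures must be positive")
    width = 0.42 * length
    half_cells = int(np.floor(width / 2 / spacing))
    x = np.arange(-half_cells, half_cells + 1) * spacing  # grid contains x = 0
    y = np.arange(0.0, length + spacing / 2, spacing)
    xx, yy = np.meshgrid(x, y)

    def snap(v: float) -> float:
        return float(np.round(v / spacing) * spacing)

    medial = 1.0 if side == "right" else -1.0
    heel_c = (snap(0.0), snap(0.15 * length))
    fore_c = (snap(medial * 0.08 * length), snap(0.72 * length))
    s_heel = (0.09 * length, 0.09 * length)
    s_fore = (0.11 * length, 0.08 * length)
    heel = peak_heel * np.exp(-(((xx - heel_c[0]) / s_heel[0]) ** 2
                                + ((yy - heel_c[1]) / s_heel[1]) ** 2))
    fore = peak_forefoot * np.exp(-(((xx - fore_c[0]) / s_fore[0]) ** 2
                                    + ((yy - fore_c[1]) / s_fore[1]) ** 2))
    values = np.maximum(heel, fore)
    # contact threshold: cells below 2% of the larger peak are unloaded
    peak = max(peak_heel, peak_forefoot)
    values[values < 0.02 * peak] = 0.0
    if noise > 0:
        rng = np.random.default_rng(seed)
        loaded = values > 0
        bump = rng.uniform(0.0, noise * peak, size=values.shape)
        # noise never raises a cell above the stated peak
        values[loaded] = np.minimum(values[loaded] + bump[loaded], peak)
    return PressureMap(x, y, values, side=side)


def _box_tets(center, dims) -> tuple[np.ndarray, np.ndarray]:
    """Tetrahedralise an axis-aligned box (corners + centre, Delaunay)."""
    from scipy.spatial import Delaunay

    center = np.asarray(center, dtype=np.float64)
    half = np.asarray(dims, dtype=np.float64) / 2.0
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)], dtype=np.float64)
    nodes = np.vstack([center + corners * half, center])
    tets = Delaunay(nodes).simplices.astype(np.int64)
    return nodes, tets


def make_volume_parts(size: float = 60.0) -> dict:
    """Small deterministic volume-mesh bundle for FE deck assembly tests.

    Builds the four model parts at toy scale: tetrahedral "bone" and
    "bulk" boxes (bone centred inside the bulk), a membrane skin sharing
    the bulk surface triangulation, and a single-layer hexahedral ground
    plate below the sole.  Node sets mark the Achilles attachment
    (posterior bone nodes) and the fixed proximal cross-sections.
    """
    from .fe_preprocess import make_skin_layer
    from .mesh_io import VolumeMesh

    s = float(size)
    bulk_nodes, bulk_tets = _box_tets([0, 0, s / 2], [s, 1.6 * s, s])
    bone_nodes, bone_tets = _box_tets([0, 0, s / 2], [0.5 * s, 0.8 * s, 0.5 * s])

    def top_nodes(nodes):
        return np.where(nodes[:, 2] >= nodes[:, 2].max() - 1e-9)[0]

    bone = VolumeMesh(bone_nodes, tet4=bone_tets,
                      element_sets={"MERGED_BONE": ("tet4", np.arange(len(bone_tets)))},
                      node_sets={
                          "ACHILLES_ATTACHMENT": np.where(
                              bone_nodes[:, 1] <= bone_nodes[:, 1].min() + 1e-9)[0],
                          "PROXIMAL_TIBIA_FIBULA": top_nodes(bone_nodes),
                      })
    bulk = VolumeMesh(bulk_nodes, tet4=bulk_tets,
                      element_sets={"BULK_SOFT_TISSUE": ("tet4", np.arange(len(bulk_tets)))})
    box = trimesh.creation.box(extents=[s, 1.6 * s, s],
                               transform=trimesh.transformations.translation_matrix(
                                   [0, 0, s / 2]))
    skin = make_skin_layer(TriangleSurfaceMesh(
        np.asarray(box.vertices, dtype=np.float64),
        np.asarray(box.faces, dtype=np.int64)))
    skin.node_sets["PROXIMAL_SKIN"] = top_nodes(skin.nodes)

    t = 10.0  # plate thickness, mm
    px = np.array([-s, 0.0, s])
    py = np.array([-s, 0.0, s]) * 1.6
    pz = np.array([-t, 0.0])
    gx, gy, gz = np.meshgrid(px, py, pz, indexing="ij")
    plate_nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * len(py) + j) * len(pz) + k

    hexes = []
    for i in range(len(px) - 1):
        for j in range(len(py) - 1):
            hexes.append([nid(i, j, 0), nid(i + 1, j, 0), nid(i + 1, j + 1, 0),
                          nid(i, j + 1, 0), nid(i, j, 1), nid(i + 1, j, 1),
                          nid(i + 1, j + 1, 1), nid(i, j + 1, 1)])
    plate = VolumeMesh(plate_nodes, hex8=np.asarray(hexes, dtype=np.int64),
                       element_sets={"GROUND_PLATE": ("hex8", np.arange(len(hexes)))})
    return {"merged_bone": bone, "bulk_soft_tissue": bulk,
            "skin": skin, "ground_plate": plate}
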