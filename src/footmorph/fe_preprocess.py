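"""Finite-element model assembly and Abaqus-INP-dialect deck writing.

The foot model consists of four parts: the merged bone and the
encapsulated bulk soft tissue (linear tetrahedra, C3D4), a 2-mm membrane
skin layer sharing the bulk surface nodes (M3D3), and a ground plate
(linear hexahedra, C3D8).  Balanced standing is represented by a vertical
plate force of half the body weight and an Achilles-tendon (triceps surae)
pull of a quarter of the body weight; the plate is fixed in all but the
vertical direction, and the proximal tibia/fibula/skin cross-sections are
fully fixed.  Foot-plate contact uses a friction coefficient of 0.6.

Volume meshing is delegated to external tools: this module consumes
:class:`~footmorph.mesh_io.VolumeMesh` inputs, validates them against the
target element sizes (3 mm bone, 5 mm soft tissue and plate), and emits a
deterministic solver-ready input deck.  Solving is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .materials import LinearElasticMaterial, OgdenN1Material, PolynomialN2Material
from .mesh_io import TriangleSurfaceMesh, VolumeMesh

logger = logging.getLogger(__name__)

__all__ = [
    "FEModelSpec",
    "MeshSizeReport",
    "build_model_spec",
    "make_skin_layer",
    "write_inp",
    "read_inp_summary",
    "convergence_ladder",
]

PART_NAMES = ("merged_bone", "bulk_soft_tissue", "skin", "ground_plate")

#: Default per-part target element edge lengths (mm).
DEFAULT_MESH_TARGETS = {
    "merged_bone": 3.0,
    "bulk_soft_tissue": 5.0,
    "skin": 5.0,
    "ground_plate": 5.0,
}

#: Mesh-convergence acceptance rule recorded alongside ladder specs.
CONVERGENCE_RULE = "peak plantar pressure deviation < 5% between successive sizes"


@dataclass
class FEModelSpec:
    """Complete model specification ready for deck export."""

    parts: dict                      # name -> VolumeMesh
    materials: dict                  # part name -> material object
    body_weight: float               # N
    friction: float = 0.6
    skin_thickness: float = 2.0      # mm
    mesh_targets: dict = field(default_factory=lambda: dict(DEFAULT_MESH_TARGETS))
    achilles_node_set: str = "ACHILLES_ATTACHMENT"
    fixed_node_sets: tuple = ("PROXIMAL_TIBIA_FIBULA", "PROXIMAL_SKIN")
    plate_load_node_set: str = "PLATE_LOAD"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PART_NAMES:
            if name not in self.parts:
                raise ValueError(f"missing part {name!r}")
            if name not in self.materials:
                raise ValueError(f"part {name!r} has no material")
        if not self.body_weight > 0:
            raise ValueError("body weight must be positive")
        if not self.skin_thickness > 0:
            raise ValueError("skin thickness must be positive")

    @property
    def plate_load(self) -> float:
        """Vertical plate force (N): half the body weight."""
        return self.body_weight / 2.0

    @property
    def achilles_load(self) -> float:
        """Achilles tendon force (N): a quarter of the body weight."""
        return self.body_weight / 4.0


@dataclass(frozen=True)
class MeshSizeReport:
    """Per-part element inventory with basic size/quality measures."""

    element_counts: dict             # part -> {element kind -> count}
    median_edge_length: dict         # part -> mm
    quality: dict                    # part -> (min, max) tet edge-length ratio
    materials: dict                  # part -> material name

    @property
    def total_elements(self) -> int:
        return sum(sum(kinds.values()) for kinds in self.element_counts.values())


def build_model_spec(parts: dict, body_weight: float,
                     overrides: Optional[dict] = None) -> FEModelSpec:
    """Assemble the model specification with study defaults.

    ``parts`` maps the four part names to their meshes.  Defaults: bone
    E = 10 GPa / nu = 0.34, bulk soft tissue second-order polynomial, skin
    first-order Ogden, near-rigid steel plate; friction 0.6; plate load
    body_weight/2 and Achilles load body_weight/4.  ``overrides``
    (friction, skin_thickness, materials.<part>, mesh_targets.<part>) are
    applied last and recorded in the spec provenance.
    """
    for name in PART_NAMES:
        if name not in parts:
            raise ValueError(f"missing part {name!r}")
    if not body_weight > 0:
        raise ValueError("body weight must be positive")
    materials = {
        "merged_bone": LinearElasticMaterial(),
        "bulk_soft_tissue": PolynomialN2Material(),
        "skin": OgdenN1Material(),
        # the plate only needs to be rigid relative to the foot
        "ground_plate": LinearElasticMaterial(youngs_modulus=210000.0, poissons_ratio=0.3),
    }
    spec = FEModelSpec(parts=dict(parts), materials=materials, body_weight=float(body_weight))
    applied = {}
    for key, value in (overrides or {}).items():
        if key == "friction":
            spec.friction = float(value)
        elif key == "skin_thickness":
            spec.skin_thickness = float(value)
        elif key.startswith("materials."):
            part = key.split(".", 1)[1]
            if part not in spec.materials:
                raise ValueError(f"override for unknown part {part!r}")
            spec.materials[part] = value
        elif key.startswith("mesh_targets."):
            part = key.split(".", 1)[1]
            if part not in spec.mesh_targets:
                raise ValueError(f"override for unknown part {part!r}")
            spec.mesh_targets[part] = float(value)
        else:
            raise ValueError(f"unknown override {key!r}")
        applied[key] = value if not hasattr(value, "__dict__") else repr(value)
        logger.info("override applied: %s = %r", key, value)
    spec.overrides = applied
    return spec


def make_skin_layer(bulk_surface: TriangleSurfaceMesh,
                    thickness: float = 2.0) -> VolumeMesh:
    """Membrane skin layer: one tri3 element per bulk surface triangle.

    The membrane shares the bulk surface nodes (no geometric offset); the
    thickness is carried as a section property on the deck.  The surface
    must be manifold (every edge shared by at most two triangles).
    """
    if not thickness > 0:
        raise ValueError("skin thickness must be positive")
    edges: dict[tuple[int, int], int] = {}
    for tri in bulk_surface.faces:
        for i in range(3):
            key = tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
            edges[key] = edges.get(key, 0) + 1
    if any(count > 2 for count in edges.values()):
        raise ValueError("non-manifold surface: an edge is shared by more than two triangles")
    n = len(bulk_surface.faces)
    return VolumeMesh(
        nodes=bulk_surface.vertices.copy(),
        tri3=bulk_surface.faces.copy(),
        element_sets={"SKIN": ("tri3", np.arange(n))},
    )


# ---------------------------------------------------------------------------
# deck writer

def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _material_card(name: str, material) -> list[str]:
    lines = [f"*MATERIAL, NAME={name}"]
    if isinstance(material, LinearElasticMaterial):
        lines += ["*ELASTIC",
                  f"{_fmt(material.youngs_modulus)}, {_fmt(material.poissons_ratio)}"]
    elif isinstance(material, PolynomialN2Material):
        lines += ["*HYPERELASTIC, POLYNOMIAL, N=2",
                  ", ".join(_fmt(v) for v in (material.C10, material.C01, material.D1,
                                              material.C20, material.C11, material.C02,
                                              material.D2))]
    elif isinstance(material, OgdenN1Material):
        # Abaqus's Ogden strain energy uses the same 2 mu/alpha^2 normalisation
        # as implemented here; D=0 declares the incompressible form.
        lines += ["*HYPERELASTIC, OGDEN, N=1",
                  f"{_fmt(material.mu)}, {_fmt(material.alpha)}, 0"]
    else:
        raise TypeError(f"no material card for {type(material).__name__}")
    return lines


_ELEMENT_TYPES = {"tet4": "C3D4", "hex8": "C3D8", "tri3": "M3D3"}


def write_inp(spec: FEModelSpec, path) -> Path:
    """Write the model as an Abaqus-INP-dialect deck (deterministic bytes).

    Node and element labels are numbered consecutively part by part in the
    fixed order merged_bone, bulk_soft_tissue, skin, ground_plate; the deck
    carries *NODE/*ELEMENT blocks, section and material cards, the
    foot-plate surface interaction with its friction coefficient, boundary
    cards, and concentrated loads summing exactly to the body-weight
    fractions.
    """
    path = Path(path)
    lines: list[str] = ["*HEADING", "footmorph foot model deck",
                        f"** body weight {_fmt(spec.body_weight)} N"]
    node_offset = 0
    elem_offset = 0
    node_offsets: dict[str, int] = {}
    for part in PART_NAMES:
        mesh = spec.parts[part]
        node_offsets[part] = node_offset
        pname = part.upper()
        lines.append(f"*NODE, NSET=N_{pname}")
        for i, nd in enumerate(mesh.nodes, start=node_offset + 1):
            lines.append(f"{i}, {_fmt(nd[0])}, {_fmt(nd[1])}, {_fmt(nd[2])}")
        for kind in ("tet4", "hex8", "tri3"):
            conn = getattr(mesh, kind)
            if not len(conn):
                continue
            lines.append(f"*ELEMENT, TYPE={_ELEMENT_TYPES[kind]}, ELSET={pname}")
            for j, el in enumerate(conn, start=elem_offset + 1):
                nodes = ", ".join(str(v + node_offset + 1) for v in el)
                lines.append(f"{j}, {nodes}")
            elem_offset += len(conn)
        node_offset += len(mesh.nodes)

    for part in PART_NAMES:
        pname = part.upper()
        if part == "skin":
            lines.append(f"*MEMBRANE SECTION, ELSET={pname}, MATERIAL=MAT_{pname}")
            lines.append(_fmt(spec.skin_thickness))
        else:
            lines.append(f"*SOLID SECTION, ELSET={pname}, MATERIAL=MAT_{pname}")
    for part in PART_NAMES:
        lines += _material_card(f"MAT_{part.upper()}", spec.materials[part])

    lines += ["*SURFACE INTERACTION, NAME=FOOT_PLATE", "*FRICTION",
              _fmt(spec.friction)]

    # node sets supplied on the part meshes (achilles attachment, fixed sections)
    named_sets: dict[str, list[int]] = {}
    for part in PART_NAMES:
        for set_name, idx in spec.parts[part].node_sets.items():
            labels = [int(i) + node_offsets[part] + 1 for i in np.asarray(idx).ravel()]
            named_sets.setdefault(set_name, []).extend(labels)
    for set_name in sorted(named_sets):
        lines.append(f"*NSET, NSET={set_name}")
        labels = named_sets[set_name]
        for start in range(0, len(labels), 8):
            lines.append(", ".join(str(v) for v in labels[start:start + 8]))

    lines.append("*BOUNDARY")
    lines.append("N_GROUND_PLATE, 1, 2")      # plate free only vertically (dof 3)
    for set_name in spec.fixed_node_sets:
        if set_name in named_sets:
            lines.append(f"{set_name}, 1, 3")
        else:
            logger.warning("fixed node set %r not supplied; boundary card omitted", set_name)

    lines.append("*CLOAD")
    plate_set = (spec.plate_load_node_set
                 if spec.plate_load_node_set in named_sets else "N_GROUND_PLATE")
    n_plate = (len(named_sets[plate_set]) if plate_set in named_sets
               else len(spec.parts["ground_plate"].nodes))
    per_node = spec.plate_load / n_plate
    lines.append(f"** plate load {_fmt(spec.plate_load)} N upward over {n_plate} nodes")
    lines.append(f"{plate_set}, 3, {per_node!r}")
    if spec.achilles_node_set in named_sets:
        n_ach = len(named_sets[spec.achilles_node_set])
        per_node = spec.achilles_load / n_ach
        lines.append(f"** achilles load {_fmt(spec.achilles_load)} N over {n_ach} nodes")
        lines.append(f"{spec.achilles_node_set}, 3, {per_node!r}")
    else:
        logger.warning("achilles node set %r not supplied; load card omitted",
                       spec.achilles_node_set)

    lines += ["*STEP", "*STATIC", "*END STEP"]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# deck reading (summary only)

def read_inp_summary(path) -> tuple[MeshSizeReport, dict]:
    """Parse a deck written by :func:`write_inp` into an inventory.

    Returns a :class:`MeshSizeReport` plus a dictionary with material
    names/cards, friction, and the concentrated-load sums.  Unknown
    keywords produce a logged warning and are skipped.
    """
    path = Path(path)
    nodes: dict[int, np.ndarray] = {}
    elements: dict[str, list] = {}
    elem_types: dict[str, str] = {}
    materials: dict[str, str] = {}
    sections: dict[str, str] = {}
    nsets: dict[str, list[int]] = {}
    cload_sums: dict[str, float] = {}
    friction = None
    known = ("*HEADING", "*NODE", "*ELEMENT", "*SOLID SECTION", "*MEMBRANE SECTION",
             "*MATERIAL", "*ELASTIC", "*HYPERELASTIC", "*SURFACE INTERACTION",
             "*FRICTION", "*BOUNDARY", "*CLOAD", "*NSET", "*STEP", "*STATIC",
             "*END STEP")

    mode = None
    current = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            keyword = line.split(",")[0].upper().strip()
            opts = {}
            for tok in line.split(",")[1:]:
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    opts[k.strip().upper()] = v.strip()
            if keyword not in known:
                logger.warning("unknown keyword %s skipped", keyword)
                mode = None
                continue
            if keyword == "*NODE":
                mode = "node"
            elif keyword == "*ELEMENT":
                current = opts.get("ELSET", "UNNAMED")
                elem_types[current] = opts.get("TYPE", "?")
                elements.setdefault(current, [])
                mode = "element"
            elif keyword in ("*SOLID SECTION", "*MEMBRANE SECTION"):
                sections[opts.get("ELSET", "?")] = opts.get("MATERIAL", "?")
                mode = "section"
            elif keyword == "*MATERIAL":
                current = opts.get("NAME", "?")
                materials[current] = ""
                mode = "material"
            elif keyword in ("*ELASTIC", "*HYPERELASTIC"):
                if current in materials:
                    materials[current] = keyword.lstrip("*")
                mode = "skip"
            elif keyword == "*FRICTION":
                mode = "friction"
            elif keyword == "*NSET":
                current = opts.get("NSET", "?")
                nsets.setdefault(current, [])
                mode = "nset"
            elif keyword == "*CLOAD":
                mode = "cload"
            else:
                mode = None
            continue
        if mode == "node":
            parts = [p.strip() for p in line.split(",")]
            nodes[int(parts[0])] = np.array([float(v) for v in parts[1:4]])
        elif mode == "element":
            parts = [int(p) for p in line.split(",")]
            if any(p not in nodes for p in parts[1:]):
                raise ValueError(f"malformed connectivity (undefined node) in: {line!r}")
            elements[current].append(parts[1:])
        elif mode == "friction":
            friction = float(line.split(",")[0])
        elif mode == "nset":
            nsets[current].extend(int(v) for v in line.split(",") if v.strip())
        elif mode == "cload":
            parts = [p.strip() for p in line.split(",")]
            name, magnitude = parts[0], float(parts[2])
            if name in nsets:
                total = magnitude * len(nsets[name])
            elif name.startswith("N_"):
                # node set spanning a whole part, declared on its *NODE block
                total = magnitude * _count_part_nodes(path, name)
            else:
                total = magnitude
            cload_sums[name] = cload_sums.get(name, 0.0) + total

    element_counts: dict[str, dict] = {}
    median_edge: dict[str, float] = {}
    quality: dict[str, tuple] = {}
    kind_of_type = {v: k for k, v in _ELEMENT_TYPES.items()}
    for elset, conns in elements.items():
        etype = elem_types[elset]
        kind = kind_of_type.get(etype, etype)
        element_counts.setdefault(elset.lower(), {})[kind] = len(conns)
        edge_lengths = []
        ratios = []
        for conn in conns:
            pts = np.array([nodes[i] for i in conn])
            k = len(conn)
            pairs = ([(0, 1), (1, 2), (2, 0)] if k == 3 else
                     [(a, b) for a in range(k) for b in range(a + 1, k)] if k == 4 else
                     [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
                      (0, 4), (1, 5), (2, 6), (3, 7)])
            ls = [float(np.linalg.norm(pts[a] - pts[b])) for a, b in pairs]
            edge_lengths.extend(ls)
            if k == 4:
                ratios.append(max(ls) / max(min(ls), 1e-12))
        median_edge[elset.lower()] = float(np.median(edge_lengths)) if edge_lengths else 0.0
        if ratios:
            quality[elset.lower()] = (float(min(ratios)), float(max(ratios)))
    part_materials = {elset.lower(): mat for elset, mat in sections.items()}
    report = MeshSizeReport(element_counts, median_edge, quality, part_materials)
    inventory = {
        "n_nodes": len(nodes),
        "materials": materials,
        "sections": {k.lower(): v for k, v in sections.items()},
        "friction": friction,
        "cload_sums": cload_sums,
        "node_sets": {k: len(v) for k, v in nsets.items()},
    }
    return report, inventory


def _count_part_nodes(path: Path, nset_name: str) -> int:
    count = 0
    counting = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.upper().startswith("*NODE"):
            counting = f"NSET={nset_name}" in line.upper().replace(" ", "")
            continue
        if line.startswith("*"):
            counting = False
            continue
        if counting and line and not line.startswith("**"):
            count += 1
    return count


def convergence_ladder(target_sizes: Sequence[float]) -> list[dict]:
    """Mesh-refinement ladder for an external convergence sweep.

    One spec per size (strictly decreasing, e.g. halving from 20 mm to
    1.25 mm); the acceptance rule — under 5% deviation of the peak plantar
    pressure between successive refinements — is recorded as metadata, not
    evaluated here.
    """
    sizes = [float(s) for s in target_sizes]
    if not sizes:
        raise ValueError("at least one target size required")
    if any(s <= 0 for s in sizes):
        raise ValueError("element sizes must be positive")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("element sizes must be strictly decreasing")
    return [{"element_size_mm": s,
             "mesh_targets": {part: s for part in PART_NAMES},
             "acceptance_rule": CONVERGENCE_RULE}
            for s in sizes]
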