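"""Mesh generation for the bony-prominence region of interest and verification fixtures.

The simulated domain is a two-layer soft-tissue strip (a thin, stiffer skin
layer over a much softer subcutaneous layer) whose lower surface follows a
circular arc — the contour of an underlying bony prominence such as an
ischial tuberosity — resting apex-down on a rectangular mattress block.
All meshes are structured grids of 4-node quadrilaterals, generated
programmatically; no external mesh files are ever read.

Units are mm for lengths and kPa for moduli throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialProps",
    "RoiGeometry",
    "MeshDensitySpec",
    "Mesh",
    "build_roi_mesh",
    "build_verification_mesh",
    "write_vtk",
    "mesh_to_json",
    "mesh_from_json",
]

# Grading ratios for the structured generators: target in-plane element aspect
# for each layer (skin is meshed finer than subcutis, the mattress coarser).
_SKIN_ASPECT = 1.4
_SUBCUTIS_ASPECT = 0.59
_MATTRESS_ASPECT = 0.25


@dataclass(frozen=True)
class MaterialProps:
    """Linear-elastic material constants for one model component.

    ``density`` is carried for completeness but unused: the analysis is
    quasi-static and body weight enters through the applied pressure.
    """

    elastic_modulus: float  # kPa
    poisson_ratio: float
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0:
            raise ValueError("elastic_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class RoiGeometry:
    """Dimensions of the region of interest (all lengths in mm)."""

    skin_thickness: float = 2.0
    subcutis_thickness: float = 15.0
    tissue_length: float = 60.0
    mattress_thickness: float = 50.0
    mattress_length: float = 400.0
    prominence_radius: float = 40.0
    out_of_plane_thickness: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "skin_thickness",
            "subcutis_thickness",
            "tissue_length",
            "mattress_thickness",
            "mattress_length",
            "prominence_radius",
            "out_of_plane_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prominence_radius < self.tissue_length / 2.0:
            raise ValueError(
                "prominence_radius must be >= tissue_length/2 so the arc "
                "profile stays single-valued in x"
            )
        if self.tissue_length > self.mattress_length:
            raise ValueError("tissue_length must not exceed mattress_length")


@dataclass(frozen=True)
class MeshDensitySpec:
    """Target element counts per layer plus a dyadic refinement level.

    ``refinement_level`` k multiplies the in-plane divisions derived from the
    targets by 2**k in each direction (so the quad count scales by ~4 per
    level).
    """

    skin_target_elements: int = 532
    subcutis_target_elements: int = 1519
    mattress_target_elements: int = 1250
    refinement_level: int = 0

    def __post_init__(self) -> None:
        if min(
            self.skin_target_elements,
            self.subcutis_target_elements,
            self.mattress_target_elements,
        ) <= 0:
            raise ValueError("element targets must be positive")
        if self.refinement_level < 0:
            raise ValueError("refinement_level must be >= 0")


#: Element-count targets of the reference (fully converged) mesh density.
REFERENCE_DENSITY = MeshDensitySpec(8515, 24300, 20000)


@dataclass
class Mesh:
    """2D quadrilateral mesh with named node and element sets.

    ``node_sets`` values are index arrays; edge sets (names ending in
    ``_edge`` or ``_boundary``) are ordered along the edge (by increasing x
    for horizontal edges).  ``element_sets`` partitions the elements into the
    physical components; ``midline_column`` is the vertical element column
    through the prominence apex (ordered bottom-up), stored separately
    because its elements also belong to the layer sets.
    """

    node_coords: np.ndarray  # (n, 2) float, mm
    quads: np.ndarray  # (m, 4) int, counter-clockwise
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    midline_column: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.quads)

    def corner_jacobians(self) -> np.ndarray:
        """Jacobian determinant of each quad at its 4 corners, shape (m, 4)."""
        xy = self.node_coords[self.quads]  # (m, 4, 2)
        # at corner k the bilinear Jacobian reduces to cross(edge to next
        # corner, edge to previous corner) / 4, for every k
        dets = np.empty((len(self.quads), 4))
        for k in range(4):
            e1 = xy[:, (k + 1) % 4] - xy[:, k]
            e2 = xy[:, (k - 1) % 4] - xy[:, k]
            dets[:, k] = (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]) / 4.0
        return dets

    def validate(self) -> None:
        if np.any(self.corner_jacobians() <= 0):
            raise ValueError("mesh contains degenerate or inverted quads")
        if self.element_sets:
            counts = sum(len(v) for v in self.element_sets.values())
            union = np.concatenate(list(self.element_sets.values()))
            if counts != self.n_elements or len(np.unique(union)) != counts:
                raise ValueError("element_sets do not partition the elements")


# ---------------------------------------------------------------------------
# structured-grid helpers


def _rect_grid(x0: float, y0: float, lx: float, ly: float, nx: int, ny: int):
    """Uniform rectangular grid; returns (coords, quads), nodes row-major
    (bottom row first, x increasing)."""
    xs = np.linspace(x0, x0 + lx, nx + 1)
    ys = np.linspace(y0, y0 + ly, ny + 1)
    X, Y = np.meshgrid(xs, ys)  # (ny+1, nx+1)
    coords = np.column_stack([X.ravel(), Y.ravel()])
    quads = _grid_quads(nx, ny)
    return coords, quads


def _grid_quads(nx: int, ny: int) -> np.ndarray:
    """CCW quad connectivity of an (nx x ny) structured grid with row-major
    node numbering (row stride nx+1)."""
    j, i = np.meshgrid(np.arange(nx), np.arange(ny))
    n0 = (i * (nx + 1) + j).ravel()
    return np.column_stack([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])


def _arc_strip(
    x_center: float,
    y_apex: float,
    width: float,
    radius: float,
    layer_thicknesses: list[float],
    layer_divisions: list[int],
    n_along: int,
):
    """Curved strip whose bottom edge is a circular arc (apex down at
    ``(x_center, y_apex)``) and whose layers are stacked vertically above it.

    Returns (coords, quads, row_of_layer_interface) with row-major numbering
    (bottom profile first).  Column x-positions are uniform; each column is a
    vertical line, so all quads are vertically sheared parallelogram-like
    cells with strictly positive Jacobians.
    """
    half = width / 2.0
    xi = np.linspace(-half, half, n_along + 1)
    sag = radius - np.sqrt(radius**2 - xi**2)
    # shift so the lowest node (not the continuous arc) touches y_apex:
    # with an odd column count the arc apex falls inside the centre element
    y_bottom = y_apex + sag - sag.min()
    # stack layer rows
    d_levels = [0.0]
    for t, nd in zip(layer_thicknesses, layer_divisions):
        base = d_levels[-1]
        d_levels.extend(base + t * np.arange(1, nd + 1) / nd)
    d_levels = np.asarray(d_levels)
    X = np.tile(x_center + xi, (len(d_levels), 1))
    Y = y_bottom[None, :] + d_levels[:, None]
    coords = np.column_stack([X.ravel(), Y.ravel()])
    quads = _grid_quads(n_along, len(d_levels) - 1)
    return coords, quads, layer_divisions


def _roi_divisions(geom: RoiGeometry, density: MeshDensitySpec):
    """Derive structured-grid divisions from the per-layer element targets."""
    L = geom.tissue_length
    nt_skin = int(round(np.sqrt(
        density.skin_target_elements * geom.skin_thickness * _SKIN_ASPECT / L)))
    if nt_skin < 2:
        if density.skin_target_elements < 2:
            raise ValueError(
                "skin_target_elements too small to place >= 2 elements "
                "through the skin thickness")
        nt_skin = 2
    nt_sub = max(1, int(round(np.sqrt(
        density.subcutis_target_elements * geom.subcutis_thickness
        * _SUBCUTIS_ASPECT / L))))
    n_along = int(round(0.5 * (
        density.skin_target_elements / nt_skin
        + density.subcutis_target_elements / nt_sub)))
    n_along = max(3, n_along)
    if n_along % 2 == 0:  # odd count => a well-defined centre column
        n_along += 1
    nx_mat = max(2, int(round(np.sqrt(
        density.mattress_target_elements * geom.mattress_length
        * _MATTRESS_ASPECT / geom.mattress_thickness))))
    ny_mat = max(2, int(round(density.mattress_target_elements / nx_mat)))
    mult = 2 ** density.refinement_level
    return nt_skin * mult, nt_sub * mult, n_along * mult, nx_mat * mult, ny_mat * mult


def build_roi_mesh(geom: RoiGeometry, density: MeshDensitySpec) -> Mesh:
    """Generate the two-body region-of-interest mesh.

    The tissue strip (skin stratum at the bottom, subcutis above) is centred
    above the mattress midpoint with its arc apex exactly touching the
    undeformed mattress top surface (zero initial gap).  The mattress is a
    uniform rectangular grid.  The two bodies share no nodes; they interact
    through the contact pair (slave ``skin_bottom_boundary``, master
    ``mattress_top_edge``).
    """
    nt_s, nt_c, n_al, nx_m, ny_m = _roi_divisions(geom, density)
    x_center = geom.mattress_length / 2.0
    y_top_mat = geom.mattress_thickness

    t_coords, t_quads, _ = _arc_strip(
        x_center,
        y_top_mat,
        geom.tissue_length,
        geom.prominence_radius,
        [geom.skin_thickness, geom.subcutis_thickness],
        [nt_s, nt_c],
        n_al,
    )
    m_coords, m_quads = _rect_grid(
        0.0, 0.0, geom.mattress_length, geom.mattress_thickness, nx_m, ny_m)

    n_t = len(t_coords)
    coords = np.vstack([t_coords, m_coords])
    quads = np.vstack([t_quads, m_quads + n_t])

    stride = n_al + 1
    n_rows = nt_s + nt_c + 1
    tissue_rows = np.arange(n_rows) * stride  # first node of each row

    n_tq = len(t_quads)
    el = np.arange(n_tq).reshape(nt_s + nt_c, n_al)
    skin_els = el[:nt_s].ravel()
    sub_els = el[nt_s:].ravel()
    mat_els = n_tq + np.arange(len(m_quads))

    # centre column of tissue elements (through the prominence apex)
    jc = (n_al - 1) // 2
    midline = el[:, jc].copy()

    m_stride = nx_m + 1
    mat_rows = np.arange(ny_m + 1) * m_stride

    node_sets = {
        "skin_bottom_boundary": np.arange(stride),
        "skin_subcutis_interface": tissue_rows[nt_s] + np.arange(stride),
        "tissue_top_edge": tissue_rows[-1] + np.arange(stride),
        "mattress_top_edge": n_t + mat_rows[-1] + np.arange(m_stride),
        "mattress_bottom": n_t + np.arange(m_stride),
        "mattress_sides": n_t + np.unique(np.concatenate(
            [mat_rows, mat_rows + nx_m])),
        "midline_nodes": tissue_rows + jc,
    }
    mesh = Mesh(
        node_coords=coords,
        quads=quads,
        node_sets=node_sets,
        element_sets={"skin": skin_els, "subcutis": sub_els, "mattress": mat_els},
        midline_column=midline,
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# verification fixtures

# classic 5-element irregular patch on the unit square
_PATCH_NODES = np.array([
    [0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0],
    [0.249, 0.342], [0.826, 0.288], [0.850, 0.649], [0.273, 0.750],
])
_PATCH_QUADS = np.array([
    [0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7], [4, 5, 6, 7],
])


def build_verification_mesh(kind: str, **params):
    """Build one of the small closed-form verification fixtures.

    Returns ``(mesh, meta)`` where ``meta`` carries whatever the analytic
    reference needs (dimensions, set names, closed-form inputs).

    Kinds: ``patch_test``, ``uniaxial_strip``, ``block_on_foundation``,
    ``cylinder_on_halfplane``.
    """
    if kind == "patch_test":
        mesh = Mesh(
            node_coords=_PATCH_NODES.copy(),
            quads=_PATCH_QUADS.copy(),
            node_sets={"boundary": np.array([0, 1, 2, 3])},
            element_sets={"body": np.arange(5)},
        )
        mesh.validate()
        meta = {"boundary_nodes": [0, 1, 2, 3]}
        return mesh, meta

    if kind == "uniaxial_strip":
        L = params.get("length", 10.0)
        h = params.get("height", 2.0)
        nx = params.get("nx", 20)
        ny = params.get("ny", 4)
        coords, quads = _rect_grid(0.0, 0.0, L, h, nx, ny)
        rows = np.arange(ny + 1) * (nx + 1)
        mesh = Mesh(
            node_coords=coords,
            quads=quads,
            node_sets={
                "left_edge": rows,
                "right_edge": rows + nx,
                "bottom_edge": np.arange(nx + 1),
                "top_edge": ny * (nx + 1) + np.arange(nx + 1),
            },
            element_sets={"body": np.arange(len(quads))},
        )
        mesh.validate()
        return mesh, {"length": L, "height": h}

    if kind == "block_on_foundation":
        bw = params.get("block_width", 20.0)
        bh = params.get("block_height", 10.0)
        fw = params.get("foundation_width", 60.0)
        fh = params.get("foundation_height", 20.0)
        # foundation discretization deliberately incommensurate with the
        # block's so that slave nodes never sit exactly on master vertices
        # (degenerate node-to-segment alignment)
        nxb, nyb = params.get("nxb", 16), params.get("nyb", 8)
        nxf, nyf = params.get("nxf", 47), params.get("nyf", 16)
        b_coords, b_quads = _rect_grid((fw - bw) / 2.0, fh, bw, bh, nxb, nyb)
        f_coords, f_quads = _rect_grid(0.0, 0.0, fw, fh, nxf, nyf)
        nb = len(b_coords)
        coords = np.vstack([b_coords, f_coords])
        quads = np.vstack([b_quads, f_quads + nb])
        f_rows = np.arange(nyf + 1) * (nxf + 1)
        mesh = Mesh(
            node_coords=coords,
            quads=quads,
            node_sets={
                "block_bottom": np.arange(nxb + 1),
                "block_top": nyb * (nxb + 1) + np.arange(nxb + 1),
                "foundation_top": nb + nyf * (nxf + 1) + np.arange(nxf + 1),
                "foundation_bottom": nb + np.arange(nxf + 1),
                "foundation_sides": nb + np.unique(
                    np.concatenate([f_rows, f_rows + nxf])),
            },
            element_sets={
                "block": np.arange(len(b_quads)),
                "foundation": len(b_quads) + np.arange(len(f_quads)),
            },
        )
        mesh.validate()
        return mesh, {
            "block_width": bw, "slave": "block_bottom",
            "master": "foundation_top",
        }

    if kind == "cylinder_on_halfplane":
        R = params.get("radius", 50.0)
        fw = params.get("foundation_width", 120.0)
        fh = params.get("foundation_height", 60.0)
        cw = params.get("cylinder_width", 60.0)
        ch = params.get("cylinder_height", 10.0)
        nxf, nyf = params.get("nxf", 160), params.get("nyf", 40)
        nxc, nyc = params.get("nxc", 120), params.get("nyc", 5)
        c_coords, c_quads, _ = _arc_strip(
            fw / 2.0, fh, cw, R, [ch], [nyc], nxc)
        f_coords, f_quads = _rect_grid(0.0, 0.0, fw, fh, nxf, nyf)
        nc = len(c_coords)
        coords = np.vstack([c_coords, f_coords])
        quads = np.vstack([c_quads, f_quads + nc])
        f_rows = np.arange(nyf + 1) * (nxf + 1)
        mesh = Mesh(
            node_coords=coords,
            quads=quads,
            node_sets={
                "cylinder_bottom": np.arange(nxc + 1),
                "cylinder_top": nyc * (nxc + 1) + np.arange(nxc + 1),
                "foundation_top": nc + nyf * (nxf + 1) + np.arange(nxf + 1),
                "foundation_bottom": nc + np.arange(nxf + 1),
                "foundation_sides": nc + np.unique(
                    np.concatenate([f_rows, f_rows + nxf])),
            },
            element_sets={
                "cylinder": np.arange(len(c_quads)),
                "foundation": len(c_quads) + np.arange(len(f_quads)),
            },
        )
        mesh.validate()
        return mesh, {
            "radius": R, "slave": "cylinder_bottom", "master": "foundation_top",
        }

    raise ValueError(f"unknown verification mesh kind: {kind!r}")


# ---------------------------------------------------------------------------
# export


def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh (and optional fields) as a legacy ASCII VTK file."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nskinslide mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.node_coords:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        m = mesh.n_elements
        f.write(f"CELLS {m} {5 * m}\n")
        for q in mesh.quads:
            f.write("4 " + " ".join(str(i) for i in q) + "\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("\n".join(["9"] * m) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        f.write(f"{row[0]:.9g} {row[1]:.9g} 0\n")
        if cell_data:
            f.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.9g}" for v in np.asarray(arr)) + "\n")


def mesh_to_json(mesh: Mesh, path) -> None:
    payload = {
        "node_coords": mesh.node_coords.tolist(),
        "quads": mesh.quads.tolist(),
        "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
        "element_sets": {k: v.tolist() for k, v in mesh.element_sets.items()},
        "midline_column": mesh.midline_column.tolist(),
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def mesh_from_json(path) -> Mesh:
    with open(path) as f:
        payload = json.load(f)
    return Mesh(
        node_coords=np.asarray(payload["node_coords"], float),
        quads=np.asarray(payload["quads"], int),
        node_sets={k: np.asarray(v, int)
                   for k, v in payload["node_sets"].items()},
        element_sets={k: np.asarray(v, int)
                      for k, v in payload["element_sets"].items()},
        midline_column=np.asarray(payload["midline_column"], int),
    )
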