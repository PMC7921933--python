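"""Layered axisymmetric geometry and structured graded quadrilateral meshes.

The puncture sample is the local cross-section under the probe: a cylinder of
radius ``radius`` and height ``depth`` (mm) with a thin skin band of solid
elements on top of flesh.  Coordinates are (r, z) with the axis of symmetry at
r = 0, z upward, and the probe advancing in -z from the top surface
z = depth.  Meshes are structured tensor-product quads, refined under the
probe footprint and graded toward the far boundaries, with the skin/flesh
interface always conforming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DomainSpec", "Mesh", "build_mesh", "mesh_quality", "write_vtk"]


class InfeasibleMeshError(ValueError):
    """The requested element size cannot resolve the geometry."""


@dataclass(frozen=True)
class DomainSpec:
    """Axisymmetric sample domain: 15 x 20 mm cross-section, 1 mm skin, 2 mm flat probe."""

    radius: float = 15.0
    depth: float = 20.0
    skin_thickness: float = 1.0
    probe_radius: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.skin_thickness < self.depth):
            raise ValueError("need 0 < skin_thickness < depth")
        if not (0 < self.probe_radius < self.radius):
            raise ValueError("need 0 < probe_radius < radius")


@dataclass
class Mesh:
    """Structured axisymmetric quad mesh.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array of (r, z) coordinates in mm.
    elems : (n_elems, 4) int array, counter-clockwise connectivity.
    material : (n_elems,) array of "skin" / "flesh" tags.
    active : (n_elems,) boolean array; eroded elements are False.
    nr, nz : cell counts of the underlying tensor grid.
    spec : the generating DomainSpec.
    """

    nodes: np.ndarray
    elems: np.ndarray
    material: np.ndarray
    active: np.ndarray
    nr: int
    nz: int
    spec: DomainSpec

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def node_index(self, i: int, j: int) -> int:
        """Grid node (radial index i, vertical index j) -> flat node index."""
        return j * (self.nr + 1) + i

    def top_surface_nodes(self) -> np.ndarray:
        """Flat indices of the nodes on the undeformed top surface z = depth."""
        return np.arange(self.nz * (self.nr + 1), (self.nz + 1) * (self.nr + 1))

    def bottom_nodes(self) -> np.ndarray:
        return np.arange(0, self.nr + 1)

    def axis_nodes(self) -> np.ndarray:
        return np.arange(0, self.n_nodes, self.nr + 1)

    def outer_nodes(self) -> np.ndarray:
        return np.arange(self.nr, self.n_nodes, self.nr + 1)


def _graded_sizes(length: float, h0: float, hmax: float) -> np.ndarray:
    """Cell sizes covering ``length`` starting near h0 and growing to at most hmax.

    Sizes grow geometrically (ratio <= 1.3) and the whole list is rescaled so
    the cumulative sum is exactly ``length``; the rescale factor is kept <= 1
    by rounding the cell count up, so no cell exceeds its nominal size.
    """
    if length <= 0:
        return np.zeros(0)
    if hmax <= h0 * (1 + 1e-12):
        n = int(np.ceil(length / h0 - 1e-9))
        return np.full(n, length / n)
    sizes = []
    total = 0.0
    h = h0
    while total < length - 1e-12:
        sizes.append(min(h, hmax))
        total += sizes[-1]
        h = min(h * 1.3, hmax)
    sizes = np.array(sizes)
    return sizes * (length / sizes.sum())


def _coords_from_sizes(start: float, sizes: np.ndarray) -> np.ndarray:
    return start + np.concatenate([[0.0], np.cumsum(sizes)])


def build_mesh(spec: DomainSpec, target_h: float = 0.5, refinement_ratio: float = 4.0) -> Mesh:
    """Build a graded structured quad mesh of the layered sample.

    Element edges are at most ``target_h`` under the probe footprint
    (r <= 2*probe_radius) and in the near-surface band, growing to at most
    ``refinement_ratio * target_h`` at the far boundaries.  The skin band
    z in [depth - skin_thickness, depth] is meshed with at least two element
    rows and its interface with the flesh is conforming by construction.
    """
    if target_h <= 0:
        raise ValueError("target_h must be positive")
    if refinement_ratio < 1:
        raise ValueError("refinement_ratio must be >= 1")
    if target_h > spec.skin_thickness:
        raise InfeasibleMeshError(
            f"target_h={target_h} cannot resolve the {spec.skin_thickness} mm skin band"
        )
    hmax = refinement_ratio * target_h

    # radial: uniform fine cells to 2*probe_radius, graded outward
    r_fine = min(2.0 * spec.probe_radius, spec.radius)
    n_fine = int(np.ceil(r_fine / target_h - 1e-9))
    r_sizes = np.concatenate(
        [np.full(n_fine, r_fine / n_fine), _graded_sizes(spec.radius - r_fine, target_h, hmax)]
    )
    r_coords = _coords_from_sizes(0.0, r_sizes)

    # vertical, built top-down: skin band (>= 2 rows), fine sub-surface band,
    # then graded to the bottom
    n_skin = max(2, int(np.ceil(spec.skin_thickness / target_h - 1e-9)))
    skin_sizes = np.full(n_skin, spec.skin_thickness / n_skin)
    sub_band = min(2.0 * spec.probe_radius, spec.depth - spec.skin_thickness)
    n_sub = int(np.ceil(sub_band / target_h - 1e-9))
    sub_sizes = np.full(n_sub, sub_band / n_sub) if n_sub else np.zeros(0)
    rest = spec.depth - spec.skin_thickness - sub_band
    rest_sizes = _graded_sizes(rest, target_h, hmax)
    # top-down size list -> bottom-up coordinates
    z_sizes = np.concatenate([rest_sizes[::-1], sub_sizes, skin_sizes])
    z_coords = _coords_from_sizes(0.0, z_sizes)
    z_coords[-1] = spec.depth  # exact top surface
    interface = spec.depth - spec.skin_thickness

    nr, nz = len(r_sizes), len(z_sizes)
    R, Z = np.meshgrid(r_coords, z_coords, indexing="xy")
    nodes = np.column_stack([R.ravel(), Z.ravel()])

    elems = np.empty((nr * nz, 4), dtype=np.int64)
    material = np.empty(nr * nz, dtype=object)
    e = 0
    for j in range(nz):
        for i in range(nr):
            n0 = j * (nr + 1) + i
            elems[e] = (n0, n0 + 1, n0 + nr + 2, n0 + nr + 1)
            z_mid = 0.5 * (z_coords[j] + z_coords[j + 1])
            material[e] = "skin" if z_mid > interface - 1e-12 else "flesh"
            e += 1

    return Mesh(
        nodes=nodes,
        elems=elems,
        material=material,
        active=np.ones(nr * nz, dtype=bool),
        nr=nr,
        nz=nz,
        spec=spec,
    )


def _element_geometry(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (edge lengths (n,4), corner Jacobians (n,4))."""
    xy = mesh.nodes[mesh.elems]  # (n, 4, 2)
    edges = xy[:, [1, 2, 3, 0], :] - xy  # edge vectors
    lengths = np.linalg.norm(edges, axis=2)
    # corner Jacobian = cross product of the two edges meeting at the corner
    prev = -edges[:, [3, 0, 1, 2], :]
    cross = edges[:, :, 0] * prev[:, :, 1] - edges[:, :, 1] * prev[:, :, 0]
    # scaled by the product of adjacent edge lengths -> 1 for a rectangle corner
    denom = lengths * lengths[:, [3, 0, 1, 2]]
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(denom > 0, cross / denom, 0.0)
    return lengths, scaled


def mesh_quality(mesh: Mesh) -> dict:
    """Aspect-ratio and scaled-Jacobian summary over the active elements.

    Inverted or collapsed elements are reported (``n_inverted``,
    ``inverted_elements``), not raised.
    """
    lengths, jac = _element_geometry(mesh)
    act = mesh.active
    with np.errstate(divide="ignore", invalid="ignore"):
        aspect = np.where(lengths.min(axis=1) > 0, lengths.max(axis=1) / lengths.min(axis=1), np.inf)
    min_jac = jac.min(axis=1)
    inverted = np.flatnonzero(act & (min_jac <= 0))
    return {
        "min_aspect_ratio": float(aspect[act].min()),
        "max_aspect_ratio": float(aspect[act].max()),
        "min_scaled_jacobian": float(min_jac[act].min()),
        "n_inverted": int(inverted.size),
        "inverted_elements": inverted,
    }


def write_vtk(path, mesh: Mesh, point_data: dict | None = None, cell_data: dict | None = None,
              displacements: np.ndarray | None = None) -> None:
    """Write the mesh (active elements only) as a legacy-ASCII VTK unstructured grid.

    ``displacements`` (n_nodes, 2), if given, are added to the coordinates so
    the snapshot shows the deformed configuration.  Scalar ``point_data`` /
    ``cell_data`` arrays are written as named fields; cell arrays must be
    sized over all elements and are subset to the active ones.
    """
    coords = mesh.nodes.copy()
    if displacements is not None:
        coords = coords + displacements
    act = np.flatnonzero(mesh.active)
    lines = ["# vtk DataFile Version 3.0", "punctfem snapshot", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    for r, z in coords:
        lines.append(f"{r:.9g} {z:.9g} 0")
    lines.append(f"CELLS {act.size} {5 * act.size}")
    for e in act:
        n = mesh.elems[e]
        lines.append(f"4 {n[0]} {n[1]} {n[2]} {n[3]}")
    lines.append(f"CELL_TYPES {act.size}")
    lines.extend(["9"] * act.size)  # VTK_QUAD
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(arr, dtype=float))
    if cell_data:
        lines.append(f"CELL_DATA {act.size}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(arr, dtype=float)[act])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
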