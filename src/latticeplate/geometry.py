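"""Parametric synthetic bone-plate-lattice construct and its hex mesh.

The patient geometry is replaced by a prismatic segmental-defect
surrogate that preserves the load path of a plated mandibular defect:
two cortical-bone end blocks (fully fixed at their outer faces, the
"condylar" constraint) bridged by a graft span in which a homogenised
lattice core is sandwiched between a solid Ti face plate on top and
graft bone below.  Screws are modelled as stiff bonded element columns
tying the plate into the bone blocks.  A unilateral occlusal load acts
on a contiguous patch of the top face above the defect midspan.

The mesh is a structured grid of 8-node trilinear hexahedra.  Grid
planes are forced onto every material interface and onto the load-patch
boundary, so region volumes and the patch area are exact and
refinement-independent.  Coordinates are right-handed: x along the
span, z through the thickness, origin at one fixed end; lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .materials import LatticeCell, struts_to_porosity

__all__ = ["ConstructSpec", "Mesh", "BuildError", "build_construct_mesh",
           "refine_mesh", "region_volumes", "write_vtk",
           "REGIONS", "REGION_IDS"]

REGIONS = ("bone", "plate", "lattice", "screw")
REGION_IDS = {name: i for i, name in enumerate(REGIONS)}


class BuildError(ValueError):
    """Geometric infeasibility detected while building a construct mesh."""


def _default_screws() -> tuple[float, ...]:
    return (6.0, 13.0)  # axial offsets from each outer face, mirrored


@dataclass(frozen=True)
class ConstructSpec:
    """Geometry and discretisation of the synthetic construct.

    ``screw_positions`` are axial offsets measured from the nearer outer
    face; each offset produces a mirrored pair of screw clusters, one in
    each bone block (default 2 offsets -> 4 clusters ~ 8 bicortical
    screws at 2 y-columns per cluster).
    """

    bone_block_length: float = 20.0  # mm, each end block
    defect_span: float = 40.0  # mm, bridged gap
    section_height: float = 8.0  # mm, z
    section_width: float = 8.0  # mm, y
    t_plate: float = 1.5  # solid face-plate thickness, mm
    t_lat: float = 3.5  # lattice-core thickness, mm
    d: float = 1.0  # strut diameter, mm
    a: float = 2.5  # unit-cell size, mm
    screw_positions: tuple[float, ...] = field(default_factory=_default_screws)
    screw_diameter: float = 2.5  # mm
    plate_overlap: float = 16.0  # plate extent onto each bone block, mm
    load_patch_length: float = 6.0  # mm along x, centred on midspan
    mesh_divisions: tuple[int, int, int] = (36, 4, 8)  # nx, ny, nz
    band_divisions: tuple[int, int, int] | None = (3, 3, 2)  # z layers: graft, lattice, plate
    refinement_factor: float = 1.0

    @property
    def length(self) -> float:
        return 2 * self.bone_block_length + self.defect_span

    def validate(self) -> None:
        if self.defect_span <= 0:
            raise BuildError("defect_span must be positive")
        if self.t_plate <= 0 or self.t_lat <= 0:
            raise BuildError("layer thicknesses must be positive")
        if self.t_plate + self.t_lat > self.section_height:
            raise BuildError(
                f"t_plate + t_lat = {self.t_plate + self.t_lat} mm exceeds "
                f"section_height = {self.section_height} mm")
        if any(n < 2 for n in self.mesh_divisions):
            raise BuildError("all mesh_divisions must be >= 2")
        if self.refinement_factor < 1:
            raise BuildError("refinement_factor must be >= 1")
        if not self.screw_positions:
            raise BuildError("at least one screw position is required")
        if not 0 < self.plate_overlap <= self.bone_block_length:
            raise BuildError("plate_overlap must lie in (0, bone_block_length]")
        for s in self.screw_positions:
            if not 0 < s - self.screw_diameter / 2 < s + self.screw_diameter / 2 < self.bone_block_length:
                raise BuildError(
                    f"screw at offset {s} mm (diameter {self.screw_diameter}) "
                    f"does not lie inside the {self.bone_block_length} mm bone block")
            if s + self.screw_diameter / 2 > self.plate_overlap:
                raise BuildError(
                    f"screw at offset {s} mm is not covered by the plate "
                    f"(plate_overlap = {self.plate_overlap} mm)")
        if self.load_patch_length >= self.defect_span:
            raise BuildError("load patch must lie inside the defect span")
        if self.band_divisions is not None:
            if len(self.band_divisions) != 3 or any(b < 1 for b in self.band_divisions):
                raise BuildError("band_divisions must be 3 positive layer counts")
            if sum(self.band_divisions) != self.mesh_divisions[2]:
                raise BuildError("band_divisions must sum to the z mesh division")

    def porosity(self, cell: LatticeCell = LatticeCell()) -> float:
        return struts_to_porosity(self.d, self.a, cell)


@dataclass
class Mesh:
    """Structured hexahedral mesh with region labels and named node sets."""

    nodes: np.ndarray  # (N, 3) coordinates, mm
    elements: np.ndarray  # (M, 8) connectivity, VTK hexahedron ordering
    region: np.ndarray  # (M,) int codes into REGIONS
    elem_index: np.ndarray  # (M, 3) structured (ix, iy, iz)
    node_sets: dict[str, np.ndarray]
    patch_weights: np.ndarray  # tributary areas of load_patch nodes, mm^2
    grid: tuple[np.ndarray, np.ndarray, np.ndarray]  # x, y, z plane coordinates
    spec: ConstructSpec

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_size(self) -> float:
        """Characteristic edge: cube root of the mean element volume."""
        return float(np.mean(self.element_volumes()) ** (1.0 / 3.0))

    def element_volumes(self) -> np.ndarray:
        xs, ys, zs = self.grid
        dx, dy, dz = np.diff(xs), np.diff(ys), np.diff(zs)
        ix, iy, iz = self.elem_index.T
        return dx[ix] * dy[iy] * dz[iz]

    def region_elements(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region == REGION_IDS[name])


def _allocate(total: int, widths: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` divisions across bands.

    Every band of nonzero width receives at least one division.
    """
    widths = np.asarray(widths, dtype=float)
    active = widths > 0
    if total < active.sum():
        raise BuildError(f"{total} divisions cannot cover {int(active.sum())} bands")
    shares = np.zeros_like(widths)
    shares[active] = total * widths[active] / widths[active].sum()
    counts = np.floor(shares).astype(int)
    counts[active & (counts == 0)] = 1
    rem = total - counts.sum()
    order = np.argsort(-(shares - counts))
    i = 0
    while rem != 0:
        j = order[i % len(order)]
        if widths[j] > 0 and (rem > 0 or counts[j] > 1):
            counts[j] += 1 if rem > 0 else -1
            rem += -1 if rem > 0 else 1
        i += 1
    return counts.tolist()


def _band_coords(bounds: Sequence[float], counts: Sequence[int]) -> np.ndarray:
    """Concatenated per-band uniform grids sharing the interface planes."""
    pieces = [np.array([bounds[0]])]
    for lo, hi, n in zip(bounds[:-1], bounds[1:], counts):
        if n:
            pieces.append(np.linspace(lo, hi, n + 1)[1:])
    return np.concatenate(pieces)


def _x_band_counts(spec: ConstructSpec) -> tuple[list[float], list[int]]:
    L, bbl, span = spec.length, spec.bone_block_length, spec.defect_span
    xp0 = L / 2 - spec.load_patch_length / 2
    xp1 = L / 2 + spec.load_patch_length / 2
    xpl0, xpl1 = bbl - spec.plate_overlap, L - bbl + spec.plate_overlap
    bounds = [0.0, xpl0, bbl, xp0, xp1, bbl + span, xpl1, L]
    widths = np.diff(bounds)
    return bounds, _allocate(spec.mesh_divisions[0], widths)


def _z_band_counts(spec: ConstructSpec) -> tuple[list[float], list[int]]:
    H = spec.section_height
    bounds = [0.0, H - spec.t_plate - spec.t_lat, H - spec.t_plate, H]
    if spec.band_divisions is not None:
        counts = list(spec.band_divisions)
    else:
        counts = _allocate(spec.mesh_divisions[2], np.diff(bounds))
    return bounds, counts


def build_construct_mesh(spec: ConstructSpec) -> Mesh:
    """Mesh the construct; element count equals nx * ny * nz exactly."""
    spec.validate()
    nx, ny, nz = spec.mesh_divisions
    x_bounds, x_counts = _x_band_counts(spec)
    z_bounds, z_counts = _z_band_counts(spec)
    xs = _band_coords(x_bounds, x_counts)
    ys = np.linspace(0.0, spec.section_width, ny + 1)
    zs = _band_coords(z_bounds, z_counts)
    assert len(xs) == nx + 1 and len(zs) == nz + 1

    # nodes, index-ordered x fastest, then y, then z
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                             Z.ravel(order="F")])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ix, iy, iz = ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")
    elements = np.column_stack([
        nid(ix, iy, iz), nid(ix + 1, iy, iz), nid(ix + 1, iy + 1, iz),
        nid(ix, iy + 1, iz), nid(ix, iy, iz + 1), nid(ix + 1, iy, iz + 1),
        nid(ix + 1, iy + 1, iz + 1), nid(ix, iy + 1, iz + 1)]).astype(np.int64)
    elem_index = np.column_stack([ix, iy, iz])

    # region labels from element centroids
    xc = (xs[ix] + xs[ix + 1]) / 2
    yc = (ys[iy] + ys[iy + 1]) / 2
    zc = (zs[iz] + zs[iz + 1]) / 2
    H, L = spec.section_height, spec.length
    bbl, span = spec.bone_block_length, spec.defect_span
    region = np.full(len(elements), REGION_IDS["bone"], dtype=np.int32)
    xpl0, xpl1 = bbl - spec.plate_overlap, L - bbl + spec.plate_overlap
    in_plate = (zc > H - spec.t_plate) & (xc > xpl0) & (xc < xpl1)
    in_span = (xc > bbl) & (xc < bbl + span)
    in_lat = in_span & ~in_plate & (zc > H - spec.t_plate - spec.t_lat)
    region[in_plate] = REGION_IDS["plate"]
    region[in_lat] = REGION_IDS["lattice"]

    screw_x = [s for s in spec.screw_positions] + \
              [L - s for s in spec.screw_positions]
    half = spec.screw_diameter / 2
    w_mid = spec.section_width / 2
    near_screw = np.zeros(len(elements), dtype=bool)
    for sx in screw_x:
        near_screw |= np.abs(xc - sx) <= half
    near_screw &= np.abs(yc - w_mid) <= half
    near_screw &= ~in_plate & ~in_span
    region[near_screw] = REGION_IDS["screw"]
    if not near_screw.any():
        raise BuildError("screw clusters captured no elements; refine the mesh "
                         "or enlarge screw_diameter")

    # node sets
    I, J, K = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                          np.arange(nz + 1), indexing="ij")
    I, J, K = I.ravel(order="F"), J.ravel(order="F"), K.ravel(order="F")
    fixed_end = np.flatnonzero((I == 0) | (I == nx))
    xp0, xp1 = x_bounds[3], x_bounds[4]
    on_patch = (K == nz) & (nodes[:, 0] >= xp0 - 1e-9) & (nodes[:, 0] <= xp1 + 1e-9)
    load_patch = np.flatnonzero(on_patch)

    # tributary areas restricted to the patch band (consistent lumped load
    # for uniform pressure on exactly [xp0, xp1] x [0, W])
    def trib(coords, lo, hi):
        c = np.clip(coords, lo, hi)
        left = np.empty_like(c)
        right = np.empty_like(c)
        left[0], right[-1] = 0.0, 0.0
        left[1:] = (c[1:] - c[:-1]) / 2
        right[:-1] = left[1:]
        return left + right

    px = nodes[load_patch, 0]
    py = nodes[load_patch, 1]
    x_in = xs[(xs >= xp0 - 1e-9) & (xs <= xp1 + 1e-9)]
    wx = dict(zip(x_in, trib(x_in, xp0, xp1)))
    wy = dict(zip(ys, trib(ys, 0.0, spec.section_width)))
    patch_weights = np.array([wx[x] * wy[y] for x, y in zip(px, py)])

    screw_nodes = np.unique(elements[region == REGION_IDS["screw"]])
    plate_nodes = np.unique(elements[region == REGION_IDS["plate"]])
    screw_interface = np.intersect1d(screw_nodes, plate_nodes)

    node_sets = {"fixed_end": fixed_end, "load_patch": load_patch,
                 "screw_interface": screw_interface}
    return Mesh(nodes=nodes, elements=elements, region=region,
                elem_index=elem_index, node_sets=node_sets,
                patch_weights=patch_weights, grid=(xs, ys, zs), spec=spec)


def box_mesh(lengths: Sequence[float], divisions: Sequence[int],
             region: str = "plate") -> Mesh:
    """Uniform single-region box mesh for closed-form verification.

    Node sets: the six faces ``x0 .. z1``, plus ``fixed_end`` (= x0) and
    ``load_patch`` (= x1 face with full-face tributary weights, so a
    uniform end traction is applied consistently).
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                             Z.ravel(order="F")])

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ix, iy, iz = ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")
    elements = np.column_stack([
        nid(ix, iy, iz), nid(ix + 1, iy, iz), nid(ix + 1, iy + 1, iz),
        nid(ix, iy + 1, iz), nid(ix, iy, iz + 1), nid(ix + 1, iy, iz + 1),
        nid(ix + 1, iy + 1, iz + 1), nid(ix, iy + 1, iz + 1)]).astype(np.int64)

    I, J, K = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                          np.arange(nz + 1), indexing="ij")
    I, J, K = I.ravel(order="F"), J.ravel(order="F"), K.ravel(order="F")
    node_sets = {"x0": np.flatnonzero(I == 0), "x1": np.flatnonzero(I == nx),
                 "y0": np.flatnonzero(J == 0), "y1": np.flatnonzero(J == ny),
                 "z0": np.flatnonzero(K == 0), "z1": np.flatnonzero(K == nz)}
    node_sets["fixed_end"] = node_sets["x0"]
    node_sets["load_patch"] = node_sets["x1"]

    def trib(coords):
        w = np.zeros_like(coords)
        w[1:] += np.diff(coords) / 2
        w[:-1] += np.diff(coords) / 2
        return w

    wy = dict(zip(ys, trib(ys)))
    wz = dict(zip(zs, trib(zs)))
    face = node_sets["load_patch"]
    patch_weights = np.array([wy[y] * wz[z] for _, y, z in nodes[face]])

    spec = ConstructSpec(bone_block_length=lx / 4, defect_span=lx / 2,
                         section_height=lz, section_width=ly,
                         t_plate=lz / 4, t_lat=lz / 4,
                         mesh_divisions=(nx, ny, nz), band_divisions=None)
    return Mesh(nodes=nodes, elements=elements,
                region=np.full(len(elements), REGION_IDS[region], np.int32),
                elem_index=np.column_stack([ix, iy, iz]), node_sets=node_sets,
                patch_weights=patch_weights, grid=(xs, ys, zs), spec=spec)


def refine_mesh(spec: ConstructSpec, factor: float) -> Mesh:
    """Rebuild with per-band division counts scaled by ``factor`` (ceil).

    Interface planes and node-set geometry are preserved exactly.
    """
    if factor < 1:
        raise ValueError(f"refinement factor must be >= 1, got {factor}")
    spec.validate()
    _, x_counts = _x_band_counts(spec)
    _, z_counts = _z_band_counts(spec)
    nx = sum(math.ceil(c * factor) for c in x_counts)
    ny = math.ceil(spec.mesh_divisions[1] * factor)

    def scale_z(c: int, plate_band: bool) -> int:
        # The thickness-averaged plate stress samples a |z|-shaped bending
        # profile at layer midpoints, which is exact only for even stacks;
        # keep the plate stack even under refinement.
        if plate_band and c % 2 == 0:
            return 2 * max(1, int(c / 2 * factor + 0.5))
        return math.ceil(c * factor)

    nz_bands = tuple(scale_z(c, i == 2) for i, c in enumerate(z_counts))
    refined = replace(spec, mesh_divisions=(nx, ny, sum(nz_bands)),
                      band_divisions=nz_bands, refinement_factor=factor)
    return build_construct_mesh(refined)


def region_volumes(mesh: Mesh) -> dict[str, float]:
    vols = mesh.element_volumes()
    return {name: float(vols[mesh.region == code].sum())
            for name, code in REGION_IDS.items()}


def write_vtk(mesh: Mesh, path, cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Export as legacy-ASCII VTK unstructured grid for visual inspection."""
    cell_data = {"region": mesh.region, **(cell_data or {})}
    point_data = dict(point_data or {})
    for name, ids in mesh.node_sets.items():
        mask = np.zeros(mesh.n_nodes, dtype=np.int32)
        mask[ids] = 1
        point_data.setdefault(f"set_{name}", mask)

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("latticeplate construct mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        m = mesh.n_elements
        f.write(f"CELLS {m} {9 * m}\n")
        np.savetxt(f, np.column_stack([np.full(m, 8), mesh.elements]), fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 12), fmt="%d")  # VTK_HEXAHEDRON

        f.write(f"CELL_DATA {m}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt="%d" if kind == "int" else "%.9g")
        f.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, arr, fmt="%.9g")
            else:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%d" if kind == "int" else "%.9g")
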