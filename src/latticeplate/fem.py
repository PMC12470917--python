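"""Linear-elastic finite-element solver for construct meshes.

Solves the static equilibrium system K u = F on the structured
8-node-hexahedron mesh with fully bonded interfaces, recovers
element-centred von Mises stress, and extracts the three response
summaries used by the surrogate and the optimiser:

* ``sigma_vm_max_plate`` -- peak von Mises stress in the plate region,
  averaged through the plate thickness stack before the maximum is
  taken (suppresses mesh-sensitive corner singularities);
* ``delta_max``          -- peak nodal displacement magnitude;
* ``sigma_screw_max``    -- peak von Mises stress in the screw region.

Internal units are N-mm-MPa.  Full 2x2x2 Gauss integration; sparse
direct factorisation (no iterative tolerance enters the contract).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import ConstructSpec, Mesh, REGION_IDS, REGIONS, build_construct_mesh, refine_mesh
from .materials import (CORTICAL_BONE, TI6AL4V, LatticeCell, MaterialCard,
                        PorosityLaw, effective_modulus, struts_to_porosity)

__all__ = ["LoadCase", "FEResult", "AssemblyError", "SolverError",
           "construct_material_map", "assemble_stiffness", "solve_static",
           "solve_construct", "recover_von_mises", "summarize",
           "convergence_study"]

_GAUSS = 1.0 / np.sqrt(3.0)
# natural coordinates of the 8 local nodes, VTK hexahedron ordering
_XI = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)


class AssemblyError(RuntimeError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoadCase:
    """Occlusal bite load distributed over a named node patch."""

    P: float  # magnitude, N
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    patch: str = "load_patch"

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError("load magnitude must be non-negative")
        norm = float(np.linalg.norm(self.direction))
        if norm == 0:
            raise ValueError("load direction must be a nonzero vector")
        object.__setattr__(self, "direction",
                           tuple(float(c) / norm for c in self.direction))


@dataclass
class FEResult:
    """Solved displacement field and its scalar response summaries."""

    u: np.ndarray  # (N, 3) nodal displacements, mm
    sigma_vm: np.ndarray  # (M,) element-centred von Mises stress, MPa
    sigma_vm_max_plate: float
    delta_max: float
    sigma_screw_max: float
    strain_energy: float  # N.mm
    external_work: float  # N.mm
    converged: bool = True


def construct_material_map(spec: ConstructSpec, law: PorosityLaw,
                           cell: LatticeCell = LatticeCell(),
                           ti: MaterialCard = TI6AL4V,
                           bone: MaterialCard = CORTICAL_BONE,
                           bone_scale: float = 1.0,
                           porosity_offset: float = 0.0
                           ) -> dict[str, tuple[float, float]]:
    """Region -> (E [MPa], nu) map; the lattice uses the calibrated law.

    ``bone_scale`` multiplies the bone modulus and ``porosity_offset``
    shifts the lattice porosity (both used by uncertainty propagation).
    """
    p = struts_to_porosity(spec.d, spec.a, cell) + porosity_offset
    p = float(np.clip(p, 0.0, 0.995))
    E_lat = effective_modulus(law, p) * 1e3
    return {"bone": (bone.E_mpa * bone_scale, bone.nu),
            "plate": (ti.E_mpa, ti.nu),
            "screw": (ti.E_mpa, ti.nu),
            "lattice": (E_lat, ti.nu)}


def _elastic_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic stiffness in Voigt order [xx, yy, zz, xy, yz, zx]."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] += 2 * mu
        D[..., 3 + i, 3 + i] = mu
    return D


def _element_D(mesh: Mesh, material_map: Mapping[str, tuple[float, float]],
               sel: np.ndarray | None = None) -> np.ndarray:
    region = mesh.region if sel is None else mesh.region[sel]
    E = np.empty(len(region))
    nu = np.empty(len(region))
    for code in set(np.unique(region).tolist()):
        name = REGIONS[code]
        if name not in material_map:
            raise AssemblyError(f"no material mapped for region '{name}'")
        Ei, nui = material_map[name]
        if not (Ei > 0 and 0 < nui < 0.5):
            raise AssemblyError(f"invalid material for region '{name}': "
                                f"E={Ei}, nu={nui}")
        mask = region == code
        E[mask], nu[mask] = Ei, nui
    return _elastic_matrix(E, nu)


def _gauss_gradients(coords: np.ndarray):
    """Physical shape-function gradients and Jacobians at all Gauss points.

    Returns (dN_phys list, detJ list) over the 8 integration points;
    ``coords`` is (M, 8, 3).
    """
    out = []
    for gp in _XI * _GAUSS:
        dN = np.empty((8, 3))
        for i, (xi, eta, zeta) in enumerate(_XI):
            gx, gy, gz = gp
            dN[i, 0] = 0.125 * xi * (1 + eta * gy) * (1 + zeta * gz)
            dN[i, 1] = 0.125 * eta * (1 + xi * gx) * (1 + zeta * gz)
            dN[i, 2] = 0.125 * zeta * (1 + xi * gx) * (1 + eta * gy)
        J = np.einsum("mia,ib->mab", coords, dN)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = int(np.argmax(detJ <= 0))
            raise AssemblyError(f"degenerate element {bad}: non-positive "
                                "Jacobian at an integration point")
        invJ = np.linalg.inv(J)
        dN_phys = np.einsum("ib,mba->mia", dN, invJ)
        out.append((dN_phys, detJ))
    return out


def _strain_displacement(dN_phys: np.ndarray) -> np.ndarray:
    """B matrices (M, 6, 24) from physical gradients (M, 8, 3)."""
    M = dN_phys.shape[0]
    B = np.zeros((M, 6, 24))
    gx, gy, gz = dN_phys[:, :, 0], dN_phys[:, :, 1], dN_phys[:, :, 2]
    cols = np.arange(8) * 3
    B[:, 0, cols] = gx
    B[:, 1, cols + 1] = gy
    B[:, 2, cols + 2] = gz
    B[:, 3, cols] = gy
    B[:, 3, cols + 1] = gx
    B[:, 4, cols + 1] = gz
    B[:, 4, cols + 2] = gy
    B[:, 5, cols] = gz
    B[:, 5, cols + 2] = gx
    return B


def element_stiffness(coords: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Batch of 24x24 element stiffness matrices (full integration)."""
    M = coords.shape[0]
    ke = np.zeros((M, 24, 24))
    for dN_phys, detJ in _gauss_gradients(coords):
        B = _strain_displacement(dN_phys)
        DB = np.einsum("mkl,mlj->mkj", D, B)
        ke += np.einsum("mki,mkj,m->mij", B, DB, detJ)
    return ke


def assemble_stiffness(mesh: Mesh,
                       material_map: Mapping[str, tuple[float, float]],
                       regions: Iterable[str] | None = None) -> sp.csr_matrix:
    """Assemble the global stiffness matrix K (N/mm) as sparse CSR.

    ``regions`` restricts assembly to a subset of regions (used to split
    K into bone and non-bone parts so bone-modulus scaling is a cheap
    linear combination).
    """
    if regions is None:
        sel = np.arange(mesh.n_elements)
    else:
        codes = [REGION_IDS[r] for r in regions]
        sel = np.flatnonzero(np.isin(mesh.region, codes))
    D = _element_D(mesh, material_map, sel)
    coords = mesh.nodes[mesh.elements[sel]]
    ke = element_stiffness(coords, D)
    edof = (mesh.elements[sel, :, None] * 3 + np.arange(3)).reshape(-1, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


def _load_vector(mesh: Mesh, load: LoadCase) -> np.ndarray:
    if load.patch not in mesh.node_sets:
        raise SolverError(f"mesh has no node set '{load.patch}'")
    patch = mesh.node_sets[load.patch]
    if len(patch) == 0:
        raise SolverError(f"load patch '{load.patch}' is empty")
    if load.patch == "load_patch" and len(mesh.patch_weights) == len(patch):
        w = mesh.patch_weights / mesh.patch_weights.sum()
    else:
        w = np.full(len(patch), 1.0 / len(patch))
    F = np.zeros(3 * mesh.n_nodes)
    for c, dc in enumerate(load.direction):
        F[patch * 3 + c] = load.P * w * dc
    return F


def solve_static(K: sp.csr_matrix, mesh: Mesh, load: LoadCase,
                 material_map: Mapping[str, tuple[float, float]],
                 fixed_sets: Sequence[str] = ("fixed_end",),
                 fixed_dofs: np.ndarray | None = None) -> FEResult:
    """Solve the constrained system by sparse direct factorisation.

    Constraints are homogeneous: every dof of every node in
    ``fixed_sets`` plus any explicit ``fixed_dofs`` indices (3*node+comp,
    for verification fixtures needing roller supports).
    """
    ndof = 3 * mesh.n_nodes
    fixed = [] if fixed_dofs is None else [np.asarray(fixed_dofs, dtype=np.int64)]
    for name in fixed_sets:
        nodes = mesh.node_sets[name]
        fixed.append((nodes[:, None] * 3 + np.arange(3)).ravel())
    fixed_idx = np.unique(np.concatenate(fixed)) if fixed else np.array([], int)
    free = np.setdiff1d(np.arange(ndof), fixed_idx, assume_unique=True)
    if len(free) == 0:
        raise SolverError("all degrees of freedom are fixed")

    F = _load_vector(mesh, load)
    u = np.zeros(ndof)
    try:
        lu = splu(K[free][:, free].tocsc(), permc_spec="MMD_AT_PLUS_A")
        u[free] = lu.solve(F[free])
    except RuntimeError:
        # singular constrained system: flag, do not raise (consumed by QC)
        return FEResult(u=np.full((mesh.n_nodes, 3), np.nan),
                        sigma_vm=np.full(mesh.n_elements, np.nan),
                        sigma_vm_max_plate=np.nan, delta_max=np.nan,
                        sigma_screw_max=np.nan, strain_energy=np.nan,
                        external_work=np.nan, converged=False)
    if not np.all(np.isfinite(u)):
        raise SolverError("non-finite values in the displacement solution")

    strain_energy = 0.5 * float(u @ (K @ u))
    external_work = 0.5 * float(F @ u)
    u3 = u.reshape(-1, 3)
    vm = recover_von_mises(u3, mesh, material_map)
    s_plate, d_max, s_screw = summarize_fields(u3, vm, mesh, strict=False)
    return FEResult(u=u3, sigma_vm=vm, sigma_vm_max_plate=s_plate,
                    delta_max=d_max, sigma_screw_max=s_screw,
                    strain_energy=strain_energy, external_work=external_work)


def _recovery_cache(mesh: Mesh):
    """Per-mesh cache of B matrices and Jacobians at the Gauss points.

    Geometry-only, so it is computed once per mesh and reused across the
    many solves a DOE sweep performs on the same discretisation.
    """
    cache = getattr(mesh, "_fem_recovery_cache", None)
    if cache is None:
        coords = mesh.nodes[mesh.elements]
        cache = [(_strain_displacement(dN_phys), detJ)
                 for dN_phys, detJ in _gauss_gradients(coords)]
        mesh._fem_recovery_cache = cache
    return cache


def recover_von_mises(u: np.ndarray, mesh: Mesh,
                      material_map: Mapping[str, tuple[float, float]]
                      ) -> np.ndarray:
    """Element-centred von Mises stress (MPa).

    The stress tensor is evaluated at the 2x2x2 integration points and
    volume-averaged per element before the von Mises invariant is taken.
    """
    D = _element_D(mesh, material_map)
    ue = u[mesh.elements].reshape(mesh.n_elements, 24)
    sigma = np.zeros((mesh.n_elements, 6))
    vol = np.zeros(mesh.n_elements)
    for B, detJ in _recovery_cache(mesh):
        eps = np.einsum("mkj,mj->mk", B, ue)
        sigma += np.einsum("mkl,ml,m->mk", D, eps, detJ)
        vol += detJ
    sigma /= vol[:, None]
    sxx, syy, szz, txy, tyz, tzx = sigma.T
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))


def _plate_thickness_average(vm: np.ndarray, mesh: Mesh) -> np.ndarray:
    """Mean von Mises over each (ix, iy) column of plate elements."""
    plate = mesh.region_elements("plate")
    if len(plate) == 0:
        raise SolverError("summary requested but the plate region is empty")
    ix, iy = mesh.elem_index[plate, 0], mesh.elem_index[plate, 1]
    key = ix * (mesh.elem_index[:, 1].max() + 1) + iy
    uniq, inv = np.unique(key, return_inverse=True)
    sums = np.bincount(inv, weights=vm[plate], minlength=len(uniq))
    counts = np.bincount(inv, minlength=len(uniq))
    return sums / counts


def summarize_fields(u: np.ndarray, vm: np.ndarray, mesh: Mesh,
                     strict: bool = True) -> tuple[float, float, float]:
    """Response summaries; with ``strict=False`` a missing plate or screw
    region yields NaN instead of an error (verification box meshes)."""
    delta = float(np.max(np.linalg.norm(u, axis=1)))
    try:
        s_plate = float(_plate_thickness_average(vm, mesh).max())
    except SolverError:
        if strict:
            raise
        s_plate = float("nan")
    screw = mesh.region_elements("screw")
    if len(screw) == 0:
        if strict:
            raise SolverError("summary requested but the screw region is empty")
        return s_plate, delta, float("nan")
    return s_plate, delta, float(vm[screw].max())


def summarize(result: FEResult, mesh: Mesh) -> tuple[float, float, float]:
    """(sigma_vm_max_plate, delta_max, sigma_screw_max) of a solved result."""
    return summarize_fields(result.u, result.sigma_vm, mesh)


def solve_construct(spec: ConstructSpec, law: PorosityLaw, load: LoadCase,
                    cell: LatticeCell = LatticeCell(),
                    bone_scale: float = 1.0, porosity_offset: float = 0.0,
                    mesh: Mesh | None = None) -> FEResult:
    """Full chain: mesh -> materials -> assemble -> solve for one design."""
    if mesh is None:
        mesh = build_construct_mesh(spec)
    mat = construct_material_map(spec, law, cell=cell, bone_scale=bone_scale,
                                 porosity_offset=porosity_offset)
    K = assemble_stiffness(mesh, mat)
    return solve_static(K, mesh, load, mat)


class ReusableSolver:
    """Factorise once, solve many load cases on the same stiffness.

    Used by the DOE sweep, where designs sharing (t_lat, t_plate) share
    a mesh and the lattice/bone moduli enter K linearly, so K is a cheap
    linear combination of pre-assembled region matrices and only the
    factorisation and back-substitutions remain per design.
    """

    def __init__(self, mesh: Mesh, fixed_sets: Sequence[str] = ("fixed_end",)):
        self.mesh = mesh
        ndof = 3 * mesh.n_nodes
        fixed = [(mesh.node_sets[name][:, None] * 3 + np.arange(3)).ravel()
                 for name in fixed_sets]
        fixed_idx = np.unique(np.concatenate(fixed))
        self.free = np.setdiff1d(np.arange(ndof), fixed_idx, assume_unique=True)
        self._lu = None
        self._K = None

    def factorize(self, K: sp.csr_matrix) -> bool:
        """Returns False on a singular constrained system."""
        self._K = K
        try:
            self._lu = splu(K[self.free][:, self.free].tocsc(),
                            permc_spec="MMD_AT_PLUS_A")
            return True
        except RuntimeError:
            self._lu = None
            return False

    def solve(self, load: LoadCase,
              material_map: Mapping[str, tuple[float, float]]) -> FEResult:
        mesh = self.mesh
        if self._lu is None:
            return FEResult(u=np.full((mesh.n_nodes, 3), np.nan),
                            sigma_vm=np.full(mesh.n_elements, np.nan),
                            sigma_vm_max_plate=np.nan, delta_max=np.nan,
                            sigma_screw_max=np.nan, strain_energy=np.nan,
                            external_work=np.nan, converged=False)
        F = _load_vector(mesh, load)
        u = np.zeros(3 * mesh.n_nodes)
        u[self.free] = self._lu.solve(F[self.free])
        if not np.all(np.isfinite(u)):
            raise SolverError("non-finite values in the displacement solution")
        strain_energy = 0.5 * float(u @ (self._K @ u))
        external_work = 0.5 * float(F @ u)
        u3 = u.reshape(-1, 3)
        vm = recover_von_mises(u3, mesh, material_map)
        s_plate, d_max, s_screw = summarize_fields(u3, vm, mesh, strict=False)
        return FEResult(u=u3, sigma_vm=vm, sigma_vm_max_plate=s_plate,
                        delta_max=d_max, sigma_screw_max=s_screw,
                        strain_energy=strain_energy, external_work=external_work)


def convergence_study(spec: ConstructSpec, law: PorosityLaw, load: LoadCase,
                      factors: Sequence[float],
                      cell: LatticeCell = LatticeCell()) -> pd.DataFrame:
    """Refine the canonical mesh and tabulate the response summaries.

    Returns one row per factor with the successive relative change in
    thickness-averaged peak plate stress and peak displacement.
    """
    if len(factors) < 2:
        raise ValueError("need at least 2 refinement factors")
    rows = []
    for f in factors:
        mesh = refine_mesh(spec, f)
        res = solve_construct(spec, law, load, cell=cell, mesh=mesh)
        if not res.converged:
            raise SolverError(f"solve failed at refinement factor {f}")
        rows.append({"factor": f, "element_size": mesh.element_size,
                     "n_elements": mesh.n_elements,
                     "sigma_vm_max_plate": res.sigma_vm_max_plate,
                     "delta_max": res.delta_max})
    df = pd.DataFrame(rows)
    df["rel_change_sigma"] = df["sigma_vm_max_plate"].pct_change().abs()
    df["rel_change_delta"] = df["delta_max"].pct_change().abs()
    return df
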