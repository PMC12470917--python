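"""FE solver verification: element oracle, patch test, closed forms,
energy consistency, linearity, response summaries."""

import dataclasses

import numpy as np
import pytest

from latticeplate.fem import (AssemblyError, FEResult, LoadCase, SolverError,
                              assemble_stiffness, construct_material_map,
                              convergence_study, element_stiffness,
                              recover_von_mises, solve_construct, solve_static,
                              summarize)
from latticeplate.geometry import box_mesh, build_construct_mesh
from latticeplate.materials import PorosityLaw


def _oracle_hex_stiffness(coords, E, nu):
    """Scalar-loop 2x2x2 Gauss integration of B^T D B detJ.

    Independent of the vectorised implementation: explicit shape-function
    derivative formulas, per-point Jacobian solves, nested loops.
    """
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]])
    ke = np.zeros((24, 24))
    g = 1 / np.sqrt(3)
    for gx in (-g, g):
        for gy in (-g, g):
            for gz in (-g, g):
                dN = np.zeros((8, 3))
                for i, (sx, sy, sz) in enumerate(signs):
                    dN[i] = [sx * (1 + sy * gy) * (1 + sz * gz) / 8,
                             sy * (1 + sx * gx) * (1 + sz * gz) / 8,
                             sz * (1 + sx * gx) * (1 + sy * gy) / 8]
                J = coords.T @ dN
                detJ = np.linalg.det(J)
                grad = dN @ np.linalg.inv(J)
                B = np.zeros((6, 24))
                for i in range(8):
                    bx, by, bz = grad[i]
                    B[0, 3 * i] = bx
                    B[1, 3 * i + 1] = by
                    B[2, 3 * i + 2] = bz
                    B[3, 3 * i], B[3, 3 * i + 1] = by, bx
                    B[4, 3 * i + 1], B[4, 3 * i + 2] = bz, by
                    B[5, 3 * i], B[5, 3 * i + 2] = bz, bx
                ke += B.T @ D @ B * detJ
    return ke


class TestElementAndAssembly:
    def test_unit_cube_stiffness_matches_independent_oracle(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                           [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                          dtype=float)
        E, nu = 110e3, 0.33
        D = np.zeros((1, 6, 6))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D[0, :3, :3] = lam
        D[0, np.arange(3), np.arange(3)] += 2 * mu
        D[0, np.arange(3, 6), np.arange(3, 6)] = mu
        ke = element_stiffness(coords[None], D)[0]
        ke_ref = _oracle_hex_stiffness(coords, E, nu)
        assert np.max(np.abs(ke - ke_ref)) < 1e-10 * np.max(np.abs(ke_ref))

    def test_stiffness_symmetric_with_rigid_body_nullspace(self, small_spec,
                                                           law):
        mesh = build_construct_mesh(small_spec)
        mat = construct_material_map(small_spec, law)
        K = assemble_stiffness(mesh, mat)
        asym = abs(K - K.T).max()
        assert asym < 1e-8 * abs(K).max()
        scale = abs(K).max()
        # translations
        for c in range(3):
            t = np.zeros(3 * mesh.n_nodes)
            t[c::3] = 1.0
            assert np.max(np.abs(K @ t)) < 1e-8 * scale
        # rotations about the three axes
        x = mesh.nodes - mesh.nodes.mean(axis=0)
        for axis in np.eye(3):
            r = np.cross(np.tile(axis, (mesh.n_nodes, 1)), x).ravel()
            assert np.max(np.abs(K @ r)) < 1e-8 * scale * np.abs(r).max()

    def test_unmapped_region_rejected(self, small_spec):
        mesh = build_construct_mesh(small_spec)
        with pytest.raises(AssemblyError, match="lattice"):
            assemble_stiffness(mesh, {"bone": (13e3, 0.3),
                                      "plate": (110e3, 0.33),
                                      "screw": (110e3, 0.33)})

    def test_degenerate_element_named(self):
        mesh = box_mesh((2.0, 1.0, 1.0), (2, 1, 1))
        mesh.nodes[1, 0] = -2.0  # invert the first element
        with pytest.raises(AssemblyError, match="degenerate"):
            assemble_stiffness(mesh, {"plate": (100e3, 0.3)})


def _roller_dofs(mesh):
    """ux=0 on x0, uy=0 on y=0 plane, uz=0 on z=0 plane (exact for a
    uniform uniaxial stress state with free Poisson contraction)."""
    dofs = [mesh.node_sets["x0"] * 3,
            np.flatnonzero(mesh.nodes[:, 1] == 0) * 3 + 1,
            np.flatnonzero(mesh.nodes[:, 2] == 0) * 3 + 2]
    return np.concatenate(dofs)


class TestClosedForms:
    def test_patch_uniform_traction_exact_constant_stress(self):
        # single-material box under uniform end traction: exact constant
        # stress at any mesh density
        for divs in [(2, 2, 2), (5, 3, 2)]:
            mesh = box_mesh((10.0, 4.0, 3.0), divs)
            mat = {"plate": (110e3, 0.33)}
            K = assemble_stiffness(mesh, mat)
            P = 600.0
            res = solve_static(K, mesh, LoadCase(P, (1, 0, 0)), mat,
                               fixed_sets=(), fixed_dofs=_roller_dofs(mesh))
            sigma_exact = P / (4.0 * 3.0)
            assert res.sigma_vm == pytest.approx(sigma_exact, rel=1e-8)

    def test_bar_end_displacement_PL_over_EA(self):
        L, W, H, E = 20.0, 4.0, 4.0, 110e3
        mesh = box_mesh((L, W, H), (8, 2, 2))
        mat = {"plate": (E, 0.33)}
        K = assemble_stiffness(mesh, mat)
        P = 500.0
        res = solve_static(K, mesh, LoadCase(P, (1, 0, 0)), mat,
                           fixed_sets=(), fixed_dofs=_roller_dofs(mesh))
        end = mesh.node_sets["x1"]
        assert np.allclose(res.u[end, 0], P * L / (E * W * H), rtol=1e-6)

    def test_cantilever_fibre_stress_euler_bernoulli(self):
        # clamped at x0, tip load -z; compare midspan bending stress at
        # the top element centroid with M(x) z_c / I
        L, W, H, E = 40.0, 4.0, 4.0, 110e3
        mesh = box_mesh((L, W, H), (40, 4, 8))
        mat = {"plate": (E, 0.33)}
        K = assemble_stiffness(mesh, mat)
        P = 100.0
        res = solve_static(K, mesh, LoadCase(P, (0, 0, -1)), mat,
                           fixed_sets=("x0",))
        I = W * H ** 3 / 12
        xs, ys, zs = mesh.grid
        ix, iy, iz = mesh.elem_index.T
        xc = (xs[ix] + xs[ix + 1]) / 2
        zc = (zs[iz] + zs[iz + 1]) / 2 - H / 2
        sel = np.flatnonzero((np.abs(xc - L / 2) < L / 80) & (iz == 7) &
                             (iy == 2))
        sigma_exact = P * (L - xc[sel]) * zc[sel] / I
        assert np.allclose(res.sigma_vm[sel], np.abs(sigma_exact), rtol=0.05)


class TestConstitutiveRecovery:
    def test_hydrostatic_field_has_zero_von_mises(self):
        mesh = box_mesh((2.0, 2.0, 2.0), (2, 2, 2))
        u = 1e-3 * mesh.nodes  # eps = alpha * I
        vm = recover_von_mises(u, mesh, {"plate": (100e3, 0.3)})
        assert np.max(np.abs(vm)) < 1e-6

    def test_uniaxial_stretch_recovers_absolute_stress(self):
        # pure uniaxial strain state via nu = 0 so sigma = E * eps_xx
        mesh = box_mesh((2.0, 2.0, 2.0), (2, 2, 2))
        u = np.zeros_like(mesh.nodes)
        u[:, 0] = 1e-3 * mesh.nodes[:, 0]
        vm = recover_von_mises(u, mesh, {"plate": (100e3, 0.4999 * 0 + 1e-9)})
        assert np.allclose(vm, 100e3 * 1e-3, rtol=1e-9)


class TestStaticSolve:
    def test_zero_load_zero_response(self, small_spec, law):
        res = solve_construct(small_spec, law, LoadCase(0.0))
        assert np.all(res.u == 0)
        assert res.delta_max == 0 and res.sigma_vm_max_plate == 0

    def test_doubling_load_doubles_every_field(self, small_spec, law):
        r1 = solve_construct(small_spec, law, LoadCase(300.0))
        r2 = solve_construct(small_spec, law, LoadCase(600.0))
        assert np.allclose(r2.u, 2 * r1.u, rtol=1e-9, atol=1e-15)
        assert np.allclose(r2.sigma_vm, 2 * r1.sigma_vm, rtol=1e-9)

    def test_superposition(self, small_spec, law):
        mesh = build_construct_mesh(small_spec)
        mat = construct_material_map(small_spec, law)
        K = assemble_stiffness(mesh, mat)
        ra = solve_static(K, mesh, LoadCase(200.0), mat)
        rb = solve_static(K, mesh, LoadCase(350.0), mat)
        rab = solve_static(K, mesh, LoadCase(550.0), mat)
        assert np.allclose(ra.u + rb.u, rab.u, rtol=1e-8, atol=1e-16)

    def test_energy_consistency(self, small_spec, law):
        res = solve_construct(small_spec, law, LoadCase(600.0))
        assert res.strain_energy == pytest.approx(res.external_work, rel=1e-6)
        assert res.strain_energy > 0

    def test_softer_lattice_never_stiffens_the_construct(self, small_spec,
                                                         law):
        deltas = []
        for d in (1.15, 0.85, 0.55):  # thinner struts -> higher porosity
            spec = dataclasses.replace(small_spec, d=d)
            deltas.append(solve_construct(spec, law, LoadCase(600.0)).delta_max)
        assert np.all(np.diff(deltas) > 0)

    def test_summary_contract(self, small_spec, law):
        res = solve_construct(small_spec, law, LoadCase(600.0))
        mesh = build_construct_mesh(small_spec)
        s_plate, d_max, s_screw = summarize(res, mesh)
        assert d_max == pytest.approx(np.max(np.linalg.norm(res.u, axis=1)))
        assert s_plate > 0 and s_screw > 0

    def test_summary_requires_regions(self):
        mesh = box_mesh((4.0, 2.0, 2.0), (4, 2, 2))  # plate-only mesh
        mat = {"plate": (110e3, 0.33)}
        K = assemble_stiffness(mesh, mat)
        res = solve_static(K, mesh, LoadCase(10.0), mat, fixed_sets=("x0",))
        assert np.isnan(res.sigma_screw_max)  # solve degrades gracefully
        with pytest.raises(SolverError, match="screw"):
            summarize(res, mesh)  # the strict summary names the region


class TestConvergenceStudy:
    def test_identical_factors_identical_rows(self, small_spec, law):
        df = convergence_study(small_spec, law, LoadCase(600.0), [1.0, 1.0])
        a, b = df.iloc[0], df.iloc[1]
        assert a.sigma_vm_max_plate == b.sigma_vm_max_plate
        assert a.delta_max == b.delta_max

    def test_needs_two_factors(self, small_spec, law):
        with pytest.raises(ValueError):
            convergence_study(small_spec, law, LoadCase(600.0), [1.0])
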