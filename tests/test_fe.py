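"""Finite-element core: constitutive law, element stiffness, assembly,
patch/strip/cantilever verification, incremental solver properties."""

import numpy as np
import pytest

from skinslide import (BC, FEModel, PlaneStressMaterial, SolverSettings,
                       assemble, build_verification_mesh,
                       constitutive_plane_stress, edge_pressure_loads,
                       q4_element_stiffness, solve_quasi_static)
from skinslide.geometry import Mesh

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestConstitutive:
    def test_zero_strain_zero_stress(self):
        mat = PlaneStressMaterial(100.0, 0.3)
        assert constitutive_plane_stress((0, 0, 0), mat) == (0, 0, 0)

    def test_uniaxial_nu_zero(self):
        mat = PlaneStressMaterial(100.0, 0.0)
        sxx, syy, txy = constitutive_plane_stress((0.01, 0, 0), mat)
        assert sxx == pytest.approx(1.0)
        assert syy == pytest.approx(0.0)
        assert txy == pytest.approx(0.0)

    def test_equibiaxial_nearly_incompressible(self):
        # direct evaluation of D for E=15.2 kPa, nu=0.49, exx=eyy=0.01
        mat = PlaneStressMaterial(15.2, 0.49)
        sxx, syy, _ = constitutive_plane_stress((0.01, 0.01, 0), mat)
        expected = 15.2 * 0.01 * (1 + 0.49) / (1 - 0.49**2)
        assert sxx == pytest.approx(expected, rel=1e-12)
        assert syy == pytest.approx(expected, rel=1e-12)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ValueError):
            PlaneStressMaterial(10.0, 0.5)


class TestElementStiffness:
    def test_rigid_modes_in_null_space(self):
        K = q4_element_stiffness(UNIT_SQUARE, PlaneStressMaterial(37.0, 0.3))
        tx = np.tile([1.0, 0.0], 4)
        ty = np.tile([0.0, 1.0], 4)
        rot = np.column_stack([-UNIT_SQUARE[:, 1], UNIT_SQUARE[:, 0]]).ravel()
        for mode in (tx, ty, rot):
            assert np.abs(K @ mode).max() < 1e-12
        # exactly 3 zero-energy modes
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-10) == 3
        assert np.allclose(K, K.T)

    def test_matches_brute_force_quadrature(self):
        """Independent oracle: dense numerical integration of B^T D B on a
        distorted quad with high-order Gauss-Legendre."""
        coords = np.array([[0.0, 0.0], [1.3, 0.1], [1.1, 0.9], [-0.2, 1.2]])
        mat = PlaneStressMaterial(1.0, 0.0, 2.0)
        D = mat.d_matrix()
        gl_x, gl_w = np.polynomial.legendre.leggauss(8)
        K_ref = np.zeros((8, 8))
        for xi, wx in zip(gl_x, gl_w):
            for eta, wy in zip(gl_x, gl_w):
                dN = 0.25 * np.array(
                    [[-(1 - eta), -(1 - xi)], [(1 - eta), -(1 + xi)],
                     [(1 + eta), (1 + xi)], [-(1 + eta), (1 - xi)]])
                J = coords.T @ dN
                dN_xy = dN @ np.linalg.inv(J)
                B = np.zeros((3, 8))
                B[0, 0::2] = dN_xy[:, 0]
                B[1, 1::2] = dN_xy[:, 1]
                B[2, 0::2] = dN_xy[:, 1]
                B[2, 1::2] = dN_xy[:, 0]
                K_ref += wx * wy * np.linalg.det(J) * mat.thickness \
                    * (B.T @ D @ B)
        K = q4_element_stiffness(coords, mat)
        # bilinear integrand: 2x2 Gauss is not exact on distorted quads, but
        # should agree closely; on rectangles it is exact
        assert np.abs(K - K_ref).max() < 5e-3 * np.abs(K_ref).max()
        K_rect = q4_element_stiffness(UNIT_SQUARE * [2.0, 1.0],
                                      PlaneStressMaterial(1.0, 0.25))
        K_ref2 = np.zeros((8, 8))
        coords2 = UNIT_SQUARE * [2.0, 1.0]
        D2 = PlaneStressMaterial(1.0, 0.25).d_matrix()
        for xi, wx in zip(gl_x, gl_w):
            for eta, wy in zip(gl_x, gl_w):
                dN = 0.25 * np.array(
                    [[-(1 - eta), -(1 - xi)], [(1 - eta), -(1 + xi)],
                     [(1 + eta), (1 + xi)], [-(1 + eta), (1 - xi)]])
                J = coords2.T @ dN
                dN_xy = dN @ np.linalg.inv(J)
                B = np.zeros((3, 8))
                B[0, 0::2] = dN_xy[:, 0]
                B[1, 1::2] = dN_xy[:, 1]
                B[2, 0::2] = dN_xy[:, 1]
                B[2, 1::2] = dN_xy[:, 0]
                K_ref2 += wx * wy * np.linalg.det(J) * (B.T @ D2 @ B)
        assert np.abs(K_rect - K_ref2).max() < 1e-12

    def test_assembly_equivalence_two_squares(self):
        """A 2x1 rectangle meshed as one element vs two unit squares gives
        the same tip response for a compatible end load."""
        mat = PlaneStressMaterial(10.0, 0.0, 1.0)

        def solve(mesh):
            model = FEModel(mesh, {"body": mat})
            left = mesh.node_sets["left"]
            right = mesh.node_sets["right"]
            f = np.zeros(model.n_dof)
            f[2 * right] = 0.5  # unit end traction on height-1 edge
            pres = np.concatenate([2 * left, 2 * left + 1])
            bc = BC(pres, np.zeros(len(pres)), f)
            st = solve_quasi_static(model, lambda t: bc, [1.0])
            return st.u.reshape(-1, 2)[right, 0].mean()

        one = Mesh(np.array([[0., 0.], [2., 0.], [2., 1.], [0., 1.]]),
                   np.array([[0, 1, 2, 3]]),
                   node_sets={"left": np.array([0, 3]),
                              "right": np.array([1, 2])},
                   element_sets={"body": np.array([0])})
        two = Mesh(np.array([[0., 0.], [1., 0.], [2., 0.],
                             [0., 1.], [1., 1.], [2., 1.]]),
                   np.array([[0, 1, 4, 3], [1, 2, 5, 4]]),
                   node_sets={"left": np.array([0, 3]),
                              "right": np.array([2, 5])},
                   element_sets={"body": np.array([0, 1])})
        assert solve(one) == pytest.approx(solve(two), rel=1e-12)

    def test_degenerate_element_rejected(self):
        bad = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.1], [0.0, 1.0]])
        with pytest.raises(ValueError):
            q4_element_stiffness(bad, PlaneStressMaterial(1.0, 0.3))


class TestAssemblyAndSolve:
    def test_patch_test_exact(self, patch_fixture):
        """Irregular 5-element patch reproduces a constant-strain field to
        machine precision under linear boundary displacements."""
        mesh, _ = patch_fixture
        mat = PlaneStressMaterial(96.0, 0.25)
        model = assemble(mesh, {"body": mat})
        grad = np.array([[0.003, 0.001], [0.0005, -0.002]])
        bn = mesh.node_sets["boundary"]
        vals = mesh.node_coords[bn] @ grad.T
        bc = BC(np.concatenate([2 * bn, 2 * bn + 1]),
                np.concatenate([vals[:, 0], vals[:, 1]]),
                np.zeros(model.n_dof))
        st = solve_quasi_static(model, lambda t: bc, [1.0])
        s = st.element_stresses
        exact = constitutive_plane_stress(
            (grad[0, 0], grad[1, 1], grad[0, 1] + grad[1, 0]), mat)
        assert np.abs(s - np.array(exact)).max() < 1e-12

    def test_missing_material_rejected(self, patch_fixture):
        mesh, _ = patch_fixture
        with pytest.raises(ValueError):
            FEModel(mesh, {})

    def test_uniaxial_strip_closed_form(self, strip_fixture):
        mesh, meta = strip_fixture
        mat = PlaneStressMaterial(100.0, 0.3)
        model = assemble(mesh, {"body": mat})
        left = mesh.node_sets["left_edge"]
        right = mesh.node_sets["right_edge"]
        sigma0 = 5.0
        f = edge_pressure_loads(right[::-1], mesh.node_coords, -sigma0)
        bc = BC(np.concatenate([2 * left, [2 * left[0] + 1]]),
                np.zeros(len(left) + 1), f)
        st = solve_quasi_static(model, lambda t: bc, [1.0])
        assert np.abs(st.element_stresses[:, 0] - sigma0).max() < 1e-10
        tip = st.u.reshape(-1, 2)[right, 0]
        assert tip == pytest.approx(sigma0 * meta["length"] / mat.E,
                                    rel=1e-10)

    def test_cantilever_vs_beam_theory(self):
        """Tip deflection of a slender cantilever within 10% of PL^3/3EI."""
        mesh, meta = build_verification_mesh(
            "uniaxial_strip", length=20.0, height=1.0, nx=80, ny=4)
        mat = PlaneStressMaterial(1000.0, 0.0)
        model = assemble(mesh, {"body": mat})
        left = mesh.node_sets["left_edge"]
        right = mesh.node_sets["right_edge"]
        P = 0.01
        f = np.zeros(model.n_dof)
        f[2 * right + 1] = P / len(right)
        pres = np.concatenate([2 * left, 2 * left + 1])
        bc = BC(pres, np.zeros(len(pres)), f)
        st = solve_quasi_static(model, lambda t: bc, [1.0])
        tip = st.u.reshape(-1, 2)[right, 1].mean()
        L, h = meta["length"], meta["height"]
        exact = P * L**3 / (3.0 * mat.E * (h**3 / 12.0))
        assert tip == pytest.approx(exact, rel=0.10)

    def test_zero_load_increment_converges_immediately(self, strip_fixture):
        mesh, _ = strip_fixture
        model = assemble(mesh, {"body": PlaneStressMaterial(10.0, 0.2)})
        pres = np.concatenate([2 * mesh.node_sets["left_edge"],
                               2 * mesh.node_sets["left_edge"] + 1])
        bc = BC(pres, np.zeros(len(pres)), np.zeros(model.n_dof))
        st = solve_quasi_static(model, lambda t: bc, [1.0])
        assert st.newton_iterations_used <= 1
        assert np.all(st.u == 0)

    def test_linearity_one_vs_ten_increments(self, strip_fixture):
        """A linear frictionless problem reaches the same state whether
        loaded in 1 or 10 increments."""
        mesh, _ = strip_fixture
        mat = PlaneStressMaterial(100.0, 0.3)
        left = mesh.node_sets["left_edge"]
        right = mesh.node_sets["right_edge"]
        f1 = edge_pressure_loads(right[::-1], mesh.node_coords, -5.0)
        pres = np.concatenate([2 * left, [2 * left[0] + 1]])

        def bc_at(t):
            return BC(pres, np.zeros(len(pres)), t * f1)

        model = assemble(mesh, {"body": mat})
        u_one = solve_quasi_static(model, bc_at, [1.0]).u
        u_ten = solve_quasi_static(model, bc_at, np.linspace(0.1, 1.0, 10)).u
        assert np.abs(u_one - u_ten).max() < 1e-10

    def test_solution_independent_of_node_numbering(self, patch_fixture):
        """Permuting the node numbering leaves the physical solution
        unchanged."""
        mesh, _ = patch_fixture
        mat = PlaneStressMaterial(96.0, 0.25)
        rng = np.random.default_rng(7)
        perm = rng.permutation(mesh.n_nodes)  # new[perm[i]] = old[i]
        inv = np.argsort(perm)
        permuted = Mesh(
            node_coords=mesh.node_coords[inv],
            quads=perm[mesh.quads],
            node_sets={k: perm[v] for k, v in mesh.node_sets.items()},
            element_sets=mesh.element_sets,
        )
        grad = np.array([[0.002, -0.001], [0.001, 0.003]])

        def solve(m):
            model = assemble(m, {"body": mat})
            bn = m.node_sets["boundary"]
            vals = m.node_coords[bn] @ grad.T
            bc = BC(np.concatenate([2 * bn, 2 * bn + 1]),
                    np.concatenate([vals[:, 0], vals[:, 1]]),
                    np.zeros(model.n_dof))
            return solve_quasi_static(model, lambda t: bc, [1.0]).u.reshape(-1, 2)

        u_orig = solve(mesh)
        u_perm = solve(permuted)
        assert np.abs(u_perm[perm] - u_orig).max() < 1e-12

    def test_global_stiffness_symmetric(self, roi_mesh_coarse):
        from skinslide.experiments import _materials, RunConfig
        model = FEModel(roi_mesh_coarse, _materials(RunConfig()))
        d = (model.K - model.K.T).tocoo()
        assert np.abs(d.data).max() < 1e-10 if d.nnz else True


def test_solver_settings_validation():
    with pytest.raises(ValueError):
        SolverSettings(energy_tol=0.0)
    with pytest.raises(ValueError):
        SolverSettings(n_increments_phase1=0)
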