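import numpy as np
import pytest

from celltaxis.fem import (
    ElasticSolution,
    HexMesh,
    SensingSolver,
    apply_contraction_pressure,
    apply_sensing_loads,
    assemble_system,
    directional_strain,
    element_strains,
    hex_element_stiffness,
    membrane_strain_tensor,
    minimal_constraints,
    node_strain_tensors,
    solve_sensing,
)
from celltaxis.geometry import init_spherical_cell


def uniaxial_patch(E=10.0, nu=0.3, n=3, sigma=1.0):
    """Homogeneous cube under uniform +/-x face tractions."""
    mesh = HexMesh(30.0, 30.0, 30.0, n, n, n)
    loads = np.zeros(mesh.n_dofs)
    face_area = (30.0 / n) ** 2
    i, j, k = mesh.node_ijk(np.arange(mesh.n_nodes))
    for side, sgn in ((0, -1.0), (n, 1.0)):
        ids = np.flatnonzero(i == side)
        for nid in ids:
            jj, kk = j[nid], k[nid]
            w = (0.5 if jj in (0, n) else 1.0) * (0.5 if kk in (0, n) else 1.0)
            loads[3 * nid] += sgn * sigma * face_area * w
    return mesh, loads


class TestMesh:
    def test_counts(self, coarse_mesh):
        assert coarse_mesh.n_elems == 40 * 20 * 20
        assert coarse_mesh.n_nodes == 41 * 21 * 21

    def test_uniform_element_volume(self, coarse_mesh):
        assert coarse_mesh.element_volume == pytest.approx(10.0**3)

    def test_node_roundtrip(self, coarse_mesh):
        ids = np.arange(0, coarse_mesh.n_nodes, 97)
        i, j, k = coarse_mesh.node_ijk(ids)
        assert np.array_equal(coarse_mesh.node_id(i, j, k), ids)

    def test_invalid_mesh_rejected(self):
        with pytest.raises(ValueError):
            HexMesh(10, 10, 10, 0, 1, 1)
        with pytest.raises(ValueError):
            HexMesh(-10, 10, 10, 2, 2, 2)


class TestElementStiffness:
    def test_symmetry_and_psd(self):
        K = hex_element_stiffness(10.0, 10.0, 10.0, 0.3)
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-10 * w.max()

    def test_rigid_modes_in_nullspace(self):
        K = hex_element_stiffness(7.0, 5.0, 3.0, 0.3)
        # translations produce zero force
        for axis in range(3):
            t = np.zeros(24)
            t[axis::3] = 1.0
            assert np.abs(K @ t).max() < 1e-10 * np.abs(K).max()


class TestAssembly:
    def test_moduli_validated(self, coarse_mesh):
        with pytest.raises(ValueError):
            assemble_system(coarse_mesh, np.zeros(coarse_mesh.n_elems))
        with pytest.raises(ValueError):
            assemble_system(coarse_mesh, np.ones(3))

    def test_linearity_in_modulus(self):
        mesh = HexMesh(20, 20, 20, 2, 2, 2)
        K1 = assemble_system(mesh, np.full(mesh.n_elems, 1.0))
        K2 = assemble_system(mesh, np.full(mesh.n_elems, 2.0))
        assert np.allclose(K2.toarray(), 2 * K1.toarray())


class TestPatch:
    def test_hooke_uniaxial(self):
        # uniform sigma on two faces of a homogeneous cube: eps_x = sigma/E
        E, sigma = 10.0, 0.5
        mesh, loads = uniaxial_patch(E=E, sigma=sigma)
        sol = solve_sensing(mesh, np.full(mesh.n_elems, E), loads)
        eps_xx = sol.strains[:, 0, 0]
        assert np.allclose(eps_xx, sigma / E, rtol=1e-6)
        # transverse contraction: -nu * sigma / E
        assert np.allclose(sol.strains[:, 1, 1], -0.3 * sigma / E, rtol=1e-6)

    def test_doubling_modulus_halves_displacement(self):
        mesh, loads = uniaxial_patch()
        u1 = solve_sensing(mesh, np.full(mesh.n_elems, 10.0), loads).u
        u2 = solve_sensing(mesh, np.full(mesh.n_elems, 20.0), loads).u
        assert np.allclose(u2, u1 / 2, atol=1e-12)

    def test_zero_load_zero_displacement(self):
        mesh, _ = uniaxial_patch()
        sol = solve_sensing(mesh, np.full(mesh.n_elems, 10.0),
                            np.zeros(mesh.n_dofs))
        assert np.abs(sol.u).max() == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_sparse_matches_dense(self, n, rng):
        mesh = HexMesh(10.0 * n, 10.0 * n, 10.0 * n, n, n, n)
        E = rng.uniform(1.0, 50.0, size=mesh.n_elems)
        loads = np.zeros(mesh.n_dofs)
        # self-equilibrated random loads
        f = rng.normal(size=(mesh.n_nodes, 3))
        f -= f.mean(axis=0)
        loads[:] = f.ravel()
        K = assemble_system(mesh, E)
        fixed = minimal_constraints(mesh)
        free = np.ones(mesh.n_dofs, dtype=bool)
        free[fixed] = False
        dense = np.zeros(mesh.n_dofs)
        dense[free] = np.linalg.solve(K.toarray()[np.ix_(free, free)],
                                      loads[free])
        sparse = solve_sensing(mesh, E, loads, K=K).u.ravel()
        scale = np.abs(dense).max()
        assert np.abs(sparse - dense).max() < 1e-9 * scale


class TestSensingLoads:
    def test_single_node(self):
        mesh = HexMesh(20, 20, 20, 2, 2, 2)
        loads = apply_sensing_loads(mesh, np.array([0]),
                                    np.array([[0.0, 0.0, -1.0]]), 1.0)
        assert loads[2] == pytest.approx(-1.0)
        assert np.count_nonzero(loads) == 1

    def test_zero_force(self):
        mesh = HexMesh(20, 20, 20, 2, 2, 2)
        loads = apply_sensing_loads(mesh, np.array([0, 5]),
                                    np.array([[1.0, 0, 0], [0, 1.0, 0]]), 0.0)
        assert np.abs(loads).max() == 0.0

    def test_empty_membrane_rejected(self):
        mesh = HexMesh(20, 20, 20, 2, 2, 2)
        with pytest.raises(ValueError):
            apply_sensing_loads(mesh, np.array([]), np.zeros((0, 3)), 1.0)

    def test_spherical_cell_loads_nearly_balance(self, coarse_mesh, centered_ball):
        loads = apply_sensing_loads(coarse_mesh, centered_ball.membrane_node_ids,
                                    centered_ball.e_i, 1.0)
        total = loads.reshape(-1, 3).sum(axis=0)
        per_node = np.linalg.norm(
            loads.reshape(-1, 3)[centered_ball.membrane_node_ids], axis=1).sum()
        assert np.linalg.norm(total) / per_node < 0.05

    def test_contraction_pressure_balances_exactly(self, coarse_mesh,
                                                   centered_ball):
        loads = apply_contraction_pressure(coarse_mesh, centered_ball.elements,
                                           2.0)
        total = loads.reshape(-1, 3).sum(axis=0)
        assert np.linalg.norm(total) < 1e-9


class TestStrainExtraction:
    def test_uniform_patch_strain_recovered_at_node(self):
        E, sigma = 10.0, 0.5
        mesh, loads = uniaxial_patch(E=E, sigma=sigma)
        sol = solve_sensing(mesh, np.full(mesh.n_elems, E), loads)
        interior_node = int(mesh.node_id(1, 1, 1))
        eps = membrane_strain_tensor(sol, interior_node)
        assert eps[0, 0] == pytest.approx(sigma / E, rel=1e-6)
        assert np.allclose(eps, eps.T)

    def test_average_of_two_elements(self):
        mesh = HexMesh(20, 10, 10, 2, 1, 1)
        sol = ElasticSolution(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)),
                              strains=np.stack([np.diag([1.0, 0, 0]),
                                                np.diag([3.0, 0, 0])]))
        shared = int(mesh.node_id(1, 0, 0))
        eps = membrane_strain_tensor(sol, shared)
        assert eps[0, 0] == pytest.approx(2.0)

    def test_restrict_to(self):
        mesh = HexMesh(20, 10, 10, 2, 1, 1)
        sol = ElasticSolution(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)),
                              strains=np.stack([np.diag([1.0, 0, 0]),
                                                np.diag([3.0, 0, 0])]))
        shared = int(mesh.node_id(1, 0, 0))
        eps = membrane_strain_tensor(sol, shared, restrict_to={1})
        assert eps[0, 0] == pytest.approx(3.0)

    def test_isolated_node_rejected(self):
        mesh = HexMesh(20, 10, 10, 2, 1, 1)
        sol = ElasticSolution(mesh=mesh, u=np.zeros((mesh.n_nodes, 3)),
                              strains=np.zeros((2, 3, 3)))
        with pytest.raises(ValueError):
            membrane_strain_tensor(sol, 0, restrict_to=set())


class TestDirectionalStrain:
    def test_axis_aligned(self):
        eps = np.diag([0.4, 0.0, 0.0])
        assert directional_strain(eps, [1.0, 0, 0]) == pytest.approx(0.4)
        assert directional_strain(eps, [0, 1.0, 0]) == pytest.approx(0.0)

    def test_hydrostatic_any_direction(self, rng):
        eps = 0.2 * np.eye(3)
        for _ in range(5):
            e = rng.normal(size=3)
            e /= np.linalg.norm(e)
            assert directional_strain(eps, e) == pytest.approx(0.2)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            directional_strain(np.eye(3), [1.0, 1.0, 0.0])


class TestSensingSolver:
    def test_window_matches_full_solve(self):
        mesh = HexMesh(200, 100, 100, 20, 10, 10)
        E = 1 + 99 * mesh.element_centroids[:, 0] / 200.0
        cell = init_spherical_cell(mesh, (60, 50, 50), 20.0)
        elems = np.array(sorted(cell.elements))
        windowed = SensingSolver(mesh, E, pad=500.0)  # window == full mesh
        direct = SensingSolver(mesh, E, use_window=False)
        a = windowed.solve_membrane_strains(elems, cell.membrane_node_ids,
                                            cell.e_i, 1.0)
        b = direct.solve_membrane_strains(elems, cell.membrane_node_ids,
                                          cell.e_i, 1.0)
        assert np.abs(a - b).max() < 1e-6 * np.abs(b).max()

    def test_stiffer_substrate_smaller_strain(self, coarse_mesh):
        cell = init_spherical_cell(coarse_mesh, (200, 100, 100), 20.0)
        elems = np.array(sorted(cell.elements))
        out = {}
        for E0 in (5.0, 50.0):
            solver = SensingSolver(coarse_mesh,
                                   np.full(coarse_mesh.n_elems, E0), pad=60.0)
            eps = solver.solve_membrane_strains(elems, cell.membrane_node_ids,
                                                cell.e_i, 1.0)
            out[E0] = np.abs(np.einsum("ni,nij,nj->n", cell.e_i, eps,
                                       cell.e_i)).max()
        assert out[50.0] < out[5.0]

    def test_contraction_strains_negative(self, coarse_mesh, gradient_modulus):
        cell = init_spherical_cell(coarse_mesh, (200, 100, 100), 20.0)
        elems = np.array(sorted(cell.elements))
        solver = SensingSolver(coarse_mesh, gradient_modulus, pad=60.0)
        eps = solver.solve_membrane_strains(elems, cell.membrane_node_ids,
                                            cell.e_i, 1.0)
        ec = np.einsum("ni,nij,nj->n", cell.e_i, eps, cell.e_i)
        assert (ec < 0).all()

    def test_reflection_symmetry(self):
        mesh = HexMesh(120, 120, 120, 12, 12, 12)
        E = np.full(mesh.n_elems, 10.0)
        cell = init_spherical_cell(mesh, (60, 60, 60), 20.0)
        elems = np.array(sorted(cell.elements))
        solver = SensingSolver(mesh, E, pad=200.0)
        eps = solver.solve_membrane_strains(elems, cell.membrane_node_ids,
                                            cell.e_i, 1.0)
        ec = np.einsum("ni,nij,nj->n", cell.e_i, eps, cell.e_i)
        coords = mesh.node_coords[cell.membrane_node_ids]
        # mirror each membrane node through the x=60 plane and compare
        mirrored = coords.copy()
        mirrored[:, 0] = 120.0 - mirrored[:, 0]
        lookup = {tuple(np.round(c, 6)): v for c, v in zip(coords, ec)}
        for c, v in zip(mirrored, ec):
            assert lookup[tuple(np.round(c, 6))] == pytest.approx(v, rel=1e-5)
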