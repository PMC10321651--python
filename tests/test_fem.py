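"""Elastostatics core: element stiffness, assembly, loads, solve, recovery.

Expected values come from independent oracles coded inline (explicit
B-matrix evaluation, dense factorization, eigen-decompositions) rather than
from the implementation under test.
"""

import numpy as np
import pytest

from calvaria import fem
from calvaria.mesh import LabeledMesh, box_hex_grid, hexes_to_tets, extract_boundary_triangles

MAT = fem.Material(6000.0, 0.27)


def _single_tet_mesh(coords=None):
    coords = np.asarray(
        coords if coords is not None else [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        dtype=float,
    )
    return LabeledMesh(
        nodes=coords,
        tets=np.array([[0, 1, 2, 3]]),
        element_region=np.array(["bone"], dtype=object),
    )


def _oracle_element_stiffness(coords, E, nu):
    """Independent constant-strain-tet stiffness: K = V B^T D B with the
    B-matrix assembled from explicitly inverted barycentric gradients."""
    coords = np.asarray(coords, dtype=float)
    M = np.hstack([np.ones((4, 1)), coords])  # rows [1, x, y, z]
    V = abs(np.linalg.det(M)) / 6.0
    Minv = np.linalg.inv(M)  # gradients of shape funcs are rows 1..3 of Minv
    grads = Minv[1:, :].T  # (4, 3)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        B[0, 3 * a] = gx
        B[1, 3 * a + 1] = gy
        B[2, 3 * a + 2] = gz
        B[3, 3 * a] = gy
        B[3, 3 * a + 1] = gx
        B[4, 3 * a] = gz
        B[4, 3 * a + 2] = gx
        B[5, 3 * a + 1] = gz
        B[5, 3 * a + 2] = gy
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return V * B.T @ D @ B


class TestElementStiffness:
    def test_matches_bdb_oracle_entrywise(self):
        coords = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                  [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]]  # regular tet
        K = fem.element_stiffness(coords, fem.Material(1.0, 0.0))
        K_oracle = _oracle_element_stiffness(coords, 1.0, 0.0)
        assert np.allclose(K, K_oracle, atol=1e-12)

    def test_symmetry_and_rigid_modes(self, rng):
        coords = rng.random((4, 3))
        if np.linalg.det(np.hstack([np.ones((4, 1)), coords])) < 0:
            coords[[0, 1]] = coords[[1, 0]]
        K = fem.element_stiffness(coords, MAT)
        assert np.allclose(K, K.T, atol=1e-9)
        lam = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(lam) < 1e-9 * lam.max()) == 6
        assert np.sum(lam > 1e-9 * lam.max()) == 6
        # rigid translation produces zero strain energy
        u = np.tile(rng.random(3), 4)
        assert abs(u @ K @ u) < 1e-12 * lam.max()

    def test_mirrored_ordering_same_spectrum(self, rng):
        coords = rng.random((4, 3)) * 2
        if np.linalg.det(np.hstack([np.ones((4, 1)), coords])) < 0:
            coords[[0, 1]] = coords[[1, 0]]
        K1 = fem.element_stiffness(coords, MAT)
        mirrored = coords[[1, 0, 2, 3]]  # swapped ordering, same tet
        K2 = fem.element_stiffness(mirrored, MAT)
        assert np.allclose(np.linalg.eigvalsh(K1), np.linalg.eigvalsh(K2), atol=1e-8)

    def test_degenerate_rejected(self):
        flat = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]]
        with pytest.raises(fem.FemError):
            fem.element_stiffness(flat, MAT)


class TestAssembly:
    def test_single_element_equals_element_matrix(self):
        mesh = _single_tet_mesh()
        system = fem.assemble(mesh, {"bone": MAT})
        K_el = fem.element_stiffness(mesh.nodes, MAT)
        assert np.allclose(system.stiffness.toarray(), K_el, atol=1e-12)

    def test_two_elements_coupling_pattern(self):
        # two tets sharing a triangular face: 5 nodes, 15 coupled node pairs
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float)
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        mesh = LabeledMesh(nodes, tets, np.array(["bone", "bone"], dtype=object))
        system = fem.assemble(mesh, {"bone": MAT})
        K = system.stiffness.toarray()
        assert np.allclose(K, K.T, atol=1e-9)
        coupled = set()
        for i in range(5):
            for j in range(i, 5):
                if np.abs(K[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]).max() > 0:
                    coupled.add((i, j))
        # connectivity oracle: every pair except (0, 4) interacts
        expected = {(i, j) for i in range(5) for j in range(i, 5)} - {(0, 4)}
        assert coupled == expected

    def test_missing_material(self):
        mesh = _single_tet_mesh()
        with pytest.raises(fem.FemError, match="bone"):
            fem.assemble(mesh, {"metopic": MAT})


class TestConstraintsAndSolve:
    def test_fully_constrained_zero_solution(self, rng):
        mesh = _single_tet_mesh()
        system = fem.assemble(mesh, {"bone": MAT})
        fem.add_nodal_forces(system, rng.random((4, 3)))
        fem.apply_dirichlet(system, np.arange(4), ("x", "y", "z"))
        U, info = fem.solve(system)
        assert np.allclose(U, 0.0)

    def test_empty_node_set_and_axes_error(self):
        mesh = _single_tet_mesh()
        system = fem.assemble(mesh, {"bone": MAT})
        with pytest.raises(fem.FemError):
            fem.apply_dirichlet(system, np.array([], dtype=int), ("x",))
        with pytest.raises(fem.FemError):
            fem.apply_dirichlet(system, np.array([0]), ())

    def test_insufficient_constraints_detected(self):
        mesh = _single_tet_mesh()
        system = fem.assemble(mesh, {"bone": MAT})
        system.load_vector[:] = 0.1
        fem.apply_dirichlet(system, np.array([0]), ("x", "y", "z"))
        with pytest.raises(fem.SingularSystemError):
            fem.solve(system)

    def test_matches_dense_oracle(self, rng):
        nodes0, hexes, _ = box_hex_grid((1, 1, 1), (1, 1, 1))
        nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
        mesh = LabeledMesh(nodes, tets, np.array(["bone"] * len(tets), dtype=object))
        system = fem.assemble(mesh, {"bone": MAT})
        forces = rng.standard_normal((mesh.n_nodes, 3)) * 0.1
        base = np.flatnonzero(np.abs(nodes[:, 2]) < 1e-12)
        forces[base] = 0.0
        fem.add_nodal_forces(system, forces)
        fem.apply_dirichlet(system, base, ("x", "y", "z"))
        U, info = fem.solve(system)
        # dense factorization oracle on the reduced system
        K = system.stiffness.toarray()
        con = sorted(system.constrained_dofs)
        free = np.setdiff1d(np.arange(3 * mesh.n_nodes), con)
        u_free = np.linalg.solve(K[np.ix_(free, free)], system.load_vector[free])
        assert np.allclose(U.ravel()[free], u_free, atol=1e-9 * max(1, np.abs(u_free).max()))

    def test_linearity(self, rng):
        mesh = _single_tet_mesh()
        system = fem.assemble(mesh, {"bone": MAT})
        f = rng.random((4, 3))
        fem.add_nodal_forces(system, f)
        fem.apply_dirichlet(system, np.array([0, 1, 2]), ("x", "y", "z"))
        U1, _ = fem.solve(system)
        system2 = fem.assemble(mesh, {"bone": MAT})
        fem.add_nodal_forces(system2, 2 * f)
        fem.apply_dirichlet(system2, np.array([0, 1, 2]), ("x", "y", "z"))
        U2, _ = fem.solve(system2)
        assert np.allclose(U2, 2 * U1, rtol=1e-10, atol=1e-16)

    def test_cg_matches_direct(self, rng):
        nodes0, hexes, _ = box_hex_grid((1, 1, 1), (1, 1, 1))
        nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
        mesh = LabeledMesh(nodes, tets, np.array(["bone"] * len(tets), dtype=object))
        base = np.flatnonzero(np.abs(nodes[:, 2]) < 1e-12)
        forces = rng.standard_normal((mesh.n_nodes, 3)) * 0.1
        forces[base] = 0.0
        sols = []
        for method in ("direct", "cg"):
            system = fem.assemble(mesh, {"bone": MAT})
            fem.add_nodal_forces(system, forces)
            fem.apply_dirichlet(system, base, ("x", "y", "z"))
            U, info = fem.solve(system, method=method)
            assert info["residual"] < 1e-8
            sols.append(U)
        assert np.allclose(sols[0], sols[1], rtol=1e-7,
                           atol=1e-9 * np.abs(sols[0]).max())

    def test_unconstrained_stiffness_has_six_rigid_modes(self):
        nodes0, hexes, _ = box_hex_grid((1, 1, 1), (1, 1, 1))
        nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
        mesh = LabeledMesh(nodes, tets, np.array(["bone"] * len(tets), dtype=object))
        K = fem.assemble(mesh, {"bone": MAT}).stiffness.toarray()
        lam = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(lam) < 1e-9 * lam.max()) == 6
        assert lam[6] > 1e-9 * lam.max()

    def test_zero_load_zero_displacement(self):
        mesh = _single_tet_mesh()
        system = fem.assemble(mesh, {"bone": MAT})
        fem.apply_dirichlet(system, np.array([0, 1, 2]), ("x", "y", "z"))
        U, _ = fem.solve(system)
        assert np.allclose(U, 0.0)


class TestLoads:
    def _patch_mesh(self):
        # two equal right triangles sharing an edge, hanging off two tets
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.5, 0.5, -1]], float
        )
        tets = np.array([[0, 1, 2, 4], [1, 3, 2, 4]])
        facets = np.array([[0, 1, 2], [1, 3, 2]])
        return LabeledMesh(
            nodes, tets, np.array(["bone", "bone"], dtype=object),
            facets=facets, facet_labels=np.array(["patch", "patch"], dtype=object),
        )

    def test_point_loads_tributary_area(self):
        mesh = self._patch_mesh()
        F = np.array([3.0, -1.5, 12.0])
        forces = fem.point_loads_on_patch(mesh, "patch", F)
        assert np.allclose(forces.sum(axis=0), F, atol=1e-12)
        # shared-edge nodes (1, 2) carry double the share of corner nodes (0, 3)
        assert np.allclose(forces[1], 2 * forces[0], atol=1e-12)
        assert np.allclose(forces[2], 2 * forces[3], atol=1e-12)
        assert np.allclose(forces[4], 0.0)

    def test_point_loads_single_triangle(self):
        mesh = self._patch_mesh()
        mesh.facet_labels = np.array(["patch", "other"], dtype=object)
        forces = fem.point_loads_on_patch(mesh, "patch", np.array([0, 0, 9.0]))
        for n in (0, 1, 2):
            assert np.allclose(forces[n], [0, 0, 3.0], atol=1e-12)

    def test_empty_patch_error(self):
        mesh = self._patch_mesh()
        with pytest.raises(fem.FemError):
            fem.point_loads_on_patch(mesh, "nope", np.zeros(3))

    def test_pressure_flat_patch(self):
        mesh = self._patch_mesh()
        forces = fem.pressure_loads(mesh, "patch", 3.0)  # MPa on unit area, +z normal
        assert np.allclose(forces.sum(axis=0), [0, 0, -3.0], atol=1e-12)
        suction = fem.pressure_loads(mesh, "patch", -3.0)
        assert np.allclose(suction.sum(axis=0), [0, 0, 3.0], atol=1e-12)

    def test_pressure_closed_surface_nets_zero(self):
        nodes0, hexes, _ = box_hex_grid((1, 2, 3), (2, 2, 2))
        nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
        tris, _ = extract_boundary_triangles(tets)
        mesh = LabeledMesh(
            nodes, tets, np.array(["bone"] * len(tets), dtype=object),
            facets=tris, facet_labels=np.array(["skin"] * len(tris), dtype=object),
        )
        forces = fem.pressure_loads(mesh, "skin", 7.3)
        assert np.linalg.norm(forces.sum(axis=0)) < 1e-9


class TestRecovery:
    def _cube(self):
        nodes0, hexes, _ = box_hex_grid((1, 1, 1), (2, 2, 2))
        nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
        return LabeledMesh(nodes, tets, np.array(["bone"] * len(tets), dtype=object))

    def test_affine_field_exact_strain(self):
        mesh = self._cube()
        a = 3.7e-4
        U = np.zeros((mesh.n_nodes, 3))
        U[:, 0] = a * mesh.nodes[:, 0]
        strain = fem.recover_strain(mesh, U)
        expect = np.array([a, 0, 0, 0, 0, 0])
        assert np.allclose(strain.element_strain, expect, atol=1e-12)
        assert np.allclose(strain.node_strain, expect, atol=1e-12)

    def test_principal_ordering_and_pure_shear(self):
        diag = np.array([[3e-6, 2e-6, 1e-6, 0, 0, 0]])
        p = fem.StrainField.principal_of(diag)[0]
        assert np.allclose(p, [3e-6, 2e-6, 1e-6], atol=1e-15)
        shear = np.array([[0, 0, 0, 5e-6, 0, 0]])
        p = fem.StrainField.principal_of(shear)[0]
        assert np.allclose(p, [5e-6, 0, -5e-6], atol=1e-12)

    def test_trace_consistency(self, rng):
        mesh = self._cube()
        U = rng.standard_normal((mesh.n_nodes, 3)) * 1e-4
        strain = fem.recover_strain(mesh, U)
        tr = strain.node_strain[:, :3].sum(axis=1)
        tr_p = strain.principal.sum(axis=1)
        assert np.allclose(tr, tr_p, rtol=1e-9, atol=1e-15)


class TestStress:
    def test_uniaxial_invariants(self):
        sig = np.array([[10.0, 0, 0, 0, 0, 0]])
        vm, tresca = fem.stress_invariants(sig)
        assert np.isclose(vm[0], 10.0) and np.isclose(tresca[0], 10.0)

    def test_hydrostatic_zero_vm(self):
        sig = np.array([[4.2, 4.2, 4.2, 0, 0, 0]])
        vm, _ = fem.stress_invariants(sig)
        assert abs(vm[0]) < 1e-10

    def test_vm_matches_principal_oracle(self, rng):
        sig = rng.standard_normal((20, 6))
        vm, tresca = fem.stress_invariants(sig)
        for k in range(20):
            T = np.array(
                [[sig[k, 0], sig[k, 3], sig[k, 4]],
                 [sig[k, 3], sig[k, 1], sig[k, 5]],
                 [sig[k, 4], sig[k, 5], sig[k, 2]]]
            )
            s1, s2, s3 = sorted(np.linalg.eigvalsh(T), reverse=True)
            vm_oracle = np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))
            assert np.isclose(vm[k], vm_oracle, atol=1e-10)
            assert np.isclose(tresca[k], s1 - s3, atol=1e-10)

    def test_hooke_uniaxial_strain_to_stress(self):
        # uniaxial stress state built by hand: eps = S sigma with sigma = (10,0,0...)
        E, nu = 6000.0, 0.27
        mesh = _single_tet_mesh()
        eps = np.array([[10.0 / E, -nu * 10.0 / E, -nu * 10.0 / E, 0, 0, 0]])
        strain = fem.StrainField(eps, eps.repeat(4, axis=0), None)
        stress = fem.stress_from_strain(strain, mesh, {"bone": fem.Material(E, nu)})
        assert np.allclose(stress.element_stress[0], [10, 0, 0, 0, 0, 0], atol=1e-9)
        assert np.isclose(stress.von_mises[0], 10.0, atol=1e-9)


class TestObjectivity:
    def test_rotated_problem_rotates_solution(self, rng):
        """Frame objectivity on a small cantilever-like mesh."""
        nodes0, hexes, _ = box_hex_grid((2, 1, 1), (2, 1, 1))
        nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
        region = np.array(["bone"] * len(tets), dtype=object)
        base = np.flatnonzero(np.abs(nodes[:, 0]) < 1e-12)
        tip = np.flatnonzero(np.abs(nodes[:, 0] - 2) < 1e-12)
        forces = np.zeros((len(nodes), 3))
        forces[tip, 2] = 0.5

        def solve_case(nds, frc):
            mesh = LabeledMesh(nds, tets, region)
            system = fem.assemble(mesh, {"bone": MAT})
            fem.add_nodal_forces(system, frc)
            fem.apply_dirichlet(system, base, ("x", "y", "z"))
            U, _ = fem.solve(system)
            strain = fem.recover_strain(mesh, U)
            stress = fem.stress_from_strain(strain, mesh, {"bone": MAT})
            return U, stress.von_mises

        U0, vm0 = solve_case(nodes, forces)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        U1, vm1 = solve_case(nodes @ R.T, forces @ R.T)
        assert np.allclose(U1, U0 @ R.T, atol=1e-9)
        assert np.allclose(vm1, vm0, atol=1e-9)
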