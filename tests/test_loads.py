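"""Load-case construction: muscle forces, vectors, constraints, linearity."""

import numpy as np
import pytest

from calvaria import fem, loads
from calvaria.geometry import MuscleAttachment
from calvaria.io import ConfigError, PipelineConfig
from calvaria.mesh import LabeledMesh


class TestMuscleForce:
    @pytest.mark.parametrize(
        "csa,emg,st,expected",
        [(1.0, 1.0, 22.5, 22.5), (2.0, 0.5, 22.5, 22.5), (0.0, 0.9, 22.5, 0.0)],
    )
    def test_closed_form(self, csa, emg, st, expected):
        assert loads.muscle_force(csa, emg, st) == expected

    def test_negative_rejected(self):
        with pytest.raises(loads.LoadCaseError):
            loads.muscle_force(-1.0, 1.0, 22.5)


class TestMuscleVector:
    def _patch(self, big=3.0):
        # two triangles with areas 1/2 and big/2 sharing an edge
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [big, big, 0], [0.3, 0.3, -1]], float
        )
        tets = np.array([[0, 1, 2, 4], [1, 3, 2, 4]])
        facets = np.array([[0, 1, 2], [1, 3, 2]])
        return LabeledMesh(
            nodes, tets, np.array(["bone", "bone"], dtype=object),
            facets=facets,
            facet_labels=np.array(["attachment:deep_masseter:L"] * 2, dtype=object),
        )

    def test_unit_vector_toward_insertion(self):
        mesh = self._patch()
        att = MuscleAttachment("deep_masseter", "L", "attachment:deep_masseter:L",
                               np.array([0.0, -3.0, 0.0]))
        v = loads.muscle_vector(att, mesh)
        assert np.isclose(np.linalg.norm(v), 1.0, atol=1e-12)
        assert v[1] < 0

    def test_area_weighted_centroid(self):
        """Hand computation: triangles (0,0)(1,0)(0,1) and (1,0)(2,2)(0,1)
        have areas 1/2 and 3/2 and centroids (1/3,1/3) and (1,1), so the
        1:3 weighted patch centroid is (5/6, 5/6, 0)."""
        mesh = self._patch(big=2.0)
        from calvaria.geometry import origin_centroid

        c = origin_centroid(mesh, "attachment:deep_masseter:L")
        w = (0.5 * np.array([1 / 3, 1 / 3, 0]) + 1.5 * np.array([1.0, 1.0, 0])) / 2.0
        assert np.allclose(c, w, atol=1e-12)

    def test_coincident_centroids_error(self):
        mesh = self._patch()
        from calvaria.geometry import origin_centroid

        att = MuscleAttachment("deep_masseter", "L", "attachment:deep_masseter:L",
                               origin_centroid(mesh, "attachment:deep_masseter:L"))
        with pytest.raises(loads.LoadCaseError):
            loads.muscle_vector(att, mesh)


class TestBuildLoadCase:
    def test_pressure_only_case(self, coarse_config, coarse_mesh, coarse_attachments):
        case = loads.build_load_case("palatal_pressure_only", coarse_config,
                                     coarse_mesh, coarse_attachments)
        assert case.muscle_forces == []
        assert case.pressure[0] == "palate"
        assert np.isclose(case.pressure[1], -0.011599014, atol=1e-9)
        constrained = {s for s, _ in case.dirichlet}
        assert constrained == {"tmj_L", "tmj_R", "latch_midline"}
        assert all(axes == ("x", "y", "z") for _, axes in case.dirichlet)

    def test_single_temporalis_bilateral(self, coarse_config, coarse_mesh,
                                         coarse_attachments):
        case = loads.build_load_case("single:temporalis", coarse_config,
                                     coarse_mesh, coarse_attachments)
        assert len(case.muscle_forces) == 4
        mags = {}
        for s in case.muscle_forces:
            mags.setdefault(s.muscle, {})[s.side] = s.magnitude
        for muscle, sides in mags.items():
            assert sides["L"] == sides["R"], muscle

    def test_chewing_constraints_and_asymmetry(self, coarse_config, coarse_mesh,
                                               coarse_attachments):
        case = loads.build_load_case("chewing_R_working", coarse_config,
                                     coarse_mesh, coarse_attachments)
        axes = dict(case.dirichlet)
        assert axes["tmj_R"] == ("x", "y", "z")
        assert axes["bite_R_molar1"] == ("x", "y", "z")
        assert axes["tmj_L"] == ("x", "y")
        by = {(s.muscle, s.side): s.magnitude for s in case.muscle_forces}
        for muscle in ("deep_masseter", "anterior_temporalis"):
            assert by[(muscle, "R")] > by[(muscle, "L")]

    def test_suckling_ties_pterygoid_to_masseter(self, coarse_config, coarse_mesh,
                                                 coarse_attachments):
        case = loads.build_load_case("suckling", coarse_config, coarse_mesh,
                                     coarse_attachments)
        by = {(s.muscle, s.side): s for s in case.muscle_forces}
        mpt = by[("medial_pterygoid", "L")]
        mass_emg = coarse_config.muscles["superficial_masseter"]["emg_suckling"]
        assert mpt.emg_factor == mass_emg

    def test_unknown_case_and_missing_emg(self, coarse_config, coarse_mesh,
                                          coarse_attachments):
        with pytest.raises(loads.LoadCaseError):
            loads.build_load_case("grinding", coarse_config, coarse_mesh,
                                  coarse_attachments)
        broken = PipelineConfig()
        broken.calvarium = coarse_config.calvarium
        del broken.muscles["deep_masseter"]["emg_working"]
        with pytest.raises(ConfigError):
            loads.build_load_case("chewing_R_working", broken, coarse_mesh,
                                  coarse_attachments)

    def test_bite_point_variants(self, coarse_config, coarse_mesh, coarse_attachments):
        cfg = PipelineConfig()
        cfg.calvarium = coarse_config.calvarium
        cfg.bite_point = "lateral_incisor"
        case = loads.build_load_case("chewing_R_working", cfg, coarse_mesh,
                                     coarse_attachments)
        assert ("bite_R_lateral_incisor", ("x", "y", "z")) in case.dirichlet


class TestRealizeLoads:
    def test_muscle_resultant_exact(self, coarse_config, coarse_mesh, coarse_attachments):
        case = loads.build_load_case("single:temporalis", coarse_config,
                                     coarse_mesh, coarse_attachments)
        forces, _ = loads.realize_loads(case, coarse_mesh)
        expected = sum(s.force for s in case.muscle_forces)
        assert np.allclose(forces.sum(axis=0), expected, atol=1e-9)

    def test_bilateral_symmetry_cancels_lateral_force(self, coarse_config, coarse_mesh,
                                                      coarse_attachments):
        case = loads.build_load_case("single:masseter", coarse_config, coarse_mesh,
                                     coarse_attachments)
        forces, _ = loads.realize_loads(case, coarse_mesh)
        assert abs(forces.sum(axis=0)[2]) < 1e-9

    def test_palatal_suction_pulls_superior(self, coarse_config, coarse_mesh,
                                            coarse_attachments):
        case = loads.build_load_case("palatal_pressure_only", coarse_config,
                                     coarse_mesh, coarse_attachments)
        forces, _ = loads.realize_loads(case, coarse_mesh)
        net = forces.sum(axis=0)
        # suction on the palate underside pulls along outward (inferior)
        # normals: net force magnitude = |p| x projected area, z cancels
        tris = coarse_mesh.facets[coarse_mesh.facets_of_label("palate")]
        p = coarse_mesh.nodes[tris]
        proj_area_x = 0.5 * np.abs(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])[:, 0]
        ).sum()
        assert np.isclose(abs(net[0]), 0.011599014 * proj_area_x, rtol=1e-6)
        assert abs(net[2]) < 1e-9

    def test_zero_emg_zero_field(self, coarse_mesh, coarse_attachments, coarse_config,
                                 coarse_solver):
        cfg = PipelineConfig()
        cfg.calvarium = coarse_config.calvarium
        for m in cfg.muscles.values():
            m["emg_working"] = m["emg_balancing"] = 0.0
        case = loads.build_load_case("chewing_R_working", cfg, coarse_mesh,
                                     coarse_attachments)
        forces, dirichlet = loads.realize_loads(case, coarse_mesh)
        assert np.allclose(forces, 0.0)
        U, _ = coarse_solver.solve(
            forces, [(coarse_mesh.node_sets[s], a) for s, a in dirichlet]
        )
        assert np.allclose(U, 0.0)


class TestLinearity:
    def test_emg_scaling_scales_strain(self, coarse_mesh, coarse_attachments,
                                       coarse_config, coarse_solver):
        alpha = 0.37
        cases = []
        for scale in (1.0, alpha):
            cfg = PipelineConfig()
            cfg.calvarium = coarse_config.calvarium
            for m in cfg.muscles.values():
                for key in ("emg_working", "emg_balancing"):
                    m[key] *= scale
            case = loads.build_load_case("chewing_R_working", cfg, coarse_mesh,
                                         coarse_attachments)
            forces, dirichlet = loads.realize_loads(case, coarse_mesh)
            U, _ = coarse_solver.solve(
                forces, [(coarse_mesh.node_sets[s], a) for s, a in dirichlet]
            )
            cases.append(U)
        assert np.allclose(cases[1], alpha * cases[0], rtol=1e-9, atol=1e-14)

    def test_side_swap_mirrors_solution(self, coarse_mesh, coarse_config,
                                        coarse_attachments, coarse_solver):
        """Swapping working/balancing sides mirrors the displacement field
        through z=0 (the mesh itself is mirror symmetric)."""
        from scipy.spatial import cKDTree

        mesh = coarse_mesh
        mirror_idx = cKDTree(mesh.nodes).query(mesh.nodes * [1, 1, -1])[1]
        case = loads.build_load_case("chewing_R_working", coarse_config, mesh,
                                     coarse_attachments)
        forces, dirichlet = loads.realize_loads(case, mesh)
        resolved = [(mesh.node_sets[s], a) for s, a in dirichlet]
        U_r, _ = coarse_solver.solve(forces, resolved)

        # mirrored problem: mirror forces and constraint sets through z=0
        forces_m = (forces * [1, 1, -1])[np.argsort(mirror_idx)][np.arange(len(forces))]
        forces_m = np.zeros_like(forces)
        forces_m[mirror_idx] = forces * [1, 1, -1]
        swapped = []
        for set_name, axes in dirichlet:
            ids = mirror_idx[mesh.node_sets[set_name]]
            swapped.append((ids, axes))
        U_l, _ = coarse_solver.solve(forces_m, swapped)
        U_l_back = np.empty_like(U_l)
        U_l_back[mirror_idx] = U_l * [1, 1, -1]
        assert np.allclose(U_l_back, U_r, rtol=1e-8, atol=1e-12)
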