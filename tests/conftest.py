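"""Shared fixtures.  The coarse (9 mm) calvarium keeps solve-based tests
fast; geometry invariants that depend on resolution use the default mesh."""

from dataclasses import replace

import numpy as np
import pytest

from calvaria import fem, loads
from calvaria.geometry import CalvariumParams, build_calvarium, default_attachments
from calvaria.io import PipelineConfig


@pytest.fixture(scope="session")
def coarse_params():
    return CalvariumParams(target_edge_length=9.0)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_params):
    return build_calvarium(coarse_params)


@pytest.fixture(scope="session")
def coarse_config(coarse_params):
    cfg = PipelineConfig()
    cfg.calvarium = coarse_params
    return cfg


@pytest.fixture(scope="session")
def default_mesh():
    return build_calvarium(CalvariumParams())


@pytest.fixture(scope="session")
def coarse_attachments(coarse_mesh):
    return default_attachments(coarse_mesh)


@pytest.fixture(scope="session")
def coarse_solver(coarse_mesh, coarse_config):
    return fem.CachedSolver(coarse_mesh, coarse_config.materials)


@pytest.fixture(scope="session")
def chewing_solution(coarse_mesh, coarse_config, coarse_attachments, coarse_solver):
    """(U, info, strain) of the right-sided chew on the coarse mesh."""
    case = loads.build_load_case("chewing_R_working", coarse_config, coarse_mesh,
                                 coarse_attachments)
    forces, dirichlet = loads.realize_loads(case, coarse_mesh)
    resolved = [(coarse_mesh.node_sets[s], axes) for s, axes in dirichlet]
    U, info = coarse_solver.solve(forces, resolved)
    strain = fem.recover_strain(coarse_mesh, U)
    return U, info, strain


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
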