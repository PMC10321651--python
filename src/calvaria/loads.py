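"""Construct chewing / suckling / muscle-specific / pressure-only load cases.

Muscle force magnitude = CSA (cm^2) x specific tension (22.5 N/cm^2) x EMG
activation factor; its direction is the unit vector from the area-weighted
centroid of the muscle's cranial origin patch to its mandibular insertion
centroid.  Chewing is a right-sided (working) chew: the right TMJ and the
bite point are fixed in x, y, z and the left (balancing) TMJ in x, y only.
Suckling activates the muscles bilaterally at suckling EMG factors, applies
-87 mmHg to the hard palate, and fixes both TMJs and the midline latch
point.  The lateral pterygoid is not modeled (minimal jaw-closing role).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .geometry import MuscleAttachment, origin_centroid
from .io import PipelineConfig, ConfigError

MUSCLE_GROUPS = {
    "temporalis": ("anterior_temporalis", "posterior_temporalis"),
    "masseter": ("deep_masseter", "superficial_masseter"),
    "medial_pterygoid": ("medial_pterygoid",),
}

CASE_NAMES = (
    "chewing_R_working",
    "suckling",
    "single:temporalis",
    "single:masseter",
    "single:medial_pterygoid",
    "palatal_pressure_only",
)

_BITE_SETS = {
    "molar1": "bite_R_molar1",
    "molar2": "bite_R_molar2",
    "lateral_incisor": "bite_R_lateral_incisor",
}


class LoadCaseError(ValueError):
    pass


@dataclass(frozen=True)
class MuscleForceSpec:
    muscle: str
    side: str
    csa: float  # cm^2
    emg_factor: float
    specific_tension: float  # N/cm^2
    direction: np.ndarray  # unit vector
    origin_facets: str

    @property
    def magnitude(self) -> float:
        return self.csa * self.specific_tension * self.emg_factor

    @property
    def force(self) -> np.ndarray:
        return self.magnitude * self.direction


@dataclass
class LoadCase:
    name: str
    muscle_forces: list
    pressure: tuple | None  # (facet label, MPa)
    dirichlet: list  # (node set name, axes tuple)


def muscle_force(csa: float, emg: float, specific_tension: float) -> float:
    """Force magnitude in N: CSA x specific tension x EMG factor, exact."""
    if csa < 0 or emg < 0 or specific_tension < 0:
        raise LoadCaseError("CSA, EMG factor and specific tension must be non-negative")
    return csa * specific_tension * emg


def muscle_vector(attachment: MuscleAttachment, mesh) -> np.ndarray:
    """Unit vector from the origin-patch centroid to the insertion centroid."""
    o = origin_centroid(mesh, attachment.origin_facets)
    d = np.asarray(attachment.insertion_centroid, dtype=float) - o
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise LoadCaseError(
            f"coincident origin/insertion centroids for {attachment.muscle} {attachment.side}"
        )
    return d / norm


def _chewing_dirichlet(config: PipelineConfig):
    bite = _BITE_SETS[config.bite_point]
    out = [("tmj_R", ("x", "y", "z")), (bite, ("x", "y", "z")), ("tmj_L", ("x", "y"))]
    if config.foramen_magnum_constrained:
        out.append(("foramen_magnum", ("x", "y", "z")))
    return out


def _suckling_dirichlet(config: PipelineConfig):
    out = [
        ("tmj_L", ("x", "y", "z")),
        ("tmj_R", ("x", "y", "z")),
        ("latch_midline", ("x", "y", "z")),
    ]
    if config.foramen_magnum_constrained:
        out.append(("foramen_magnum", ("x", "y", "z")))
    return out


def build_load_case(name: str, config: PipelineConfig, mesh, attachments) -> LoadCase:
    """Assemble one of the named load cases from config + attachments."""
    by_key = {(a.muscle, a.side): a for a in attachments}

    def spec(muscle, side, emg):
        att = by_key[(muscle, side)]
        entry = config.muscles.get(muscle)
        if entry is None:
            raise ConfigError(f"missing muscle config entry {muscle!r}")
        return MuscleForceSpec(
            muscle=muscle,
            side=side,
            csa=entry["csa_cm2"],
            emg_factor=emg,
            specific_tension=config.specific_tension,
            direction=muscle_vector(att, mesh),
            origin_facets=att.origin_facets,
        )

    def emg_of(muscle, key):
        entry = config.muscles.get(muscle)
        if entry is None or key not in entry:
            raise ConfigError(f"missing EMG entry {muscle}.{key}")
        return entry[key]

    if name == "chewing_R_working":
        forces = [
            spec(m, side, emg_of(m, "emg_working" if side == "R" else "emg_balancing"))
            for m in MUSCLE_GROUPS["temporalis"] + MUSCLE_GROUPS["masseter"]
            + MUSCLE_GROUPS["medial_pterygoid"]
            for side in ("L", "R")
        ]
        return LoadCase(name, forces, None, _chewing_dirichlet(config))

    if name == "suckling":
        # medial pterygoid is activated at the same ratio as the masseter
        mass_emg = emg_of("superficial_masseter", "emg_suckling")
        forces = []
        for m in MUSCLE_GROUPS["temporalis"] + MUSCLE_GROUPS["masseter"]:
            for side in ("L", "R"):
                forces.append(spec(m, side, emg_of(m, "emg_suckling")))
        for side in ("L", "R"):
            forces.append(spec("medial_pterygoid", side, mass_emg))
        return LoadCase(
            name, forces, ("palate", config.palatal_pressure_mpa), _suckling_dirichlet(config)
        )

    if name.startswith("single:"):
        group = name.split(":", 1)[1]
        if group not in MUSCLE_GROUPS:
            raise LoadCaseError(f"unknown muscle group {group!r}")
        # activated equally bilaterally at the working-side EMG factor,
        # chewing boundary conditions
        forces = [
            spec(m, side, emg_of(m, "emg_working"))
            for m in MUSCLE_GROUPS[group]
            for side in ("L", "R")
        ]
        return LoadCase(name, forces, None, _chewing_dirichlet(config))

    if name == "palatal_pressure_only":
        return LoadCase(
            name, [], ("palate", config.palatal_pressure_mpa), _suckling_dirichlet(config)
        )

    raise LoadCaseError(f"unknown load case {name!r}; expected one of {CASE_NAMES}")


def realize_loads(case: LoadCase, mesh):
    """Turn a LoadCase into (nodal force array, dirichlet list).

    Each muscle's resultant is distributed over its origin patch by tributary
    area, every node loaded along the same centroid-to-centroid direction;
    pressure becomes facet-normal nodal forces.
    """
    forces = np.zeros((mesh.n_nodes, 3))
    for spec in case.muscle_forces:
        if spec.magnitude == 0.0:
            continue
        forces += fem.point_loads_on_patch(mesh, spec.origin_facets, spec.force)
    if case.pressure is not None:
        label, p = case.pressure
        forces += fem.pressure_loads(mesh, label, p)
    for set_name, _axes in case.dirichlet:
        if set_name not in mesh.node_sets or len(mesh.node_sets[set_name]) == 0:
            raise LoadCaseError(f"mesh is missing constraint node set {set_name!r}")
    return forces, list(case.dirichlet)


def force_table(case: LoadCase):
    """Per-muscle force table (CSA, EMG, magnitude, direction) for export."""
    import pandas as pd

    rows = []
    for s in case.muscle_forces:
        rows.append(
            dict(
                muscle=s.muscle, side=s.side, csa_cm2=s.csa, emg_factor=s.emg_factor,
                specific_tension=s.specific_tension, magnitude_N=s.magnitude,
                dir_x=s.direction[0], dir_y=s.direction[1], dir_z=s.direction[2],
            )
        )
    return pd.DataFrame(rows)


def solve_case(mesh, config: PipelineConfig, case: LoadCase):
    """Assemble, load, constrain and solve one case.

    Returns (U, info); info includes the load-case name and net applied force.
    """
    system = fem.assemble(mesh, config.materials)
    forces, dirichlet = realize_loads(case, mesh)
    fem.add_nodal_forces(system, forces)
    for set_name, axes in dirichlet:
        fem.apply_dirichlet(system, mesh.node_sets[set_name], axes)
    U, info = fem.solve(system)
    info["case"] = case.name
    info["net_applied"] = forces.sum(axis=0)
    return U, info
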