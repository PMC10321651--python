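"""Closed-form verification problems for the tetrahedral elastostatics core.

Three classical benchmarks back the solver before it is trusted on cranial
geometry:

* **Patch test** — a tet-meshed cube with affine boundary displacements must
  reproduce the exact constant strain in every element (consistency of the
  constant-strain tetrahedron).
* **Lamé thick-walled sphere** — internal pressure on a spherical shell has a
  closed-form radial displacement; the discrete solution must converge to it.
* **Cantilever** — an end-loaded prism checked against the Timoshenko
  shear-corrected tip deflection.
"""

from __future__ import annotations

import numpy as np

from . import fem
from .mesh import LabeledMesh, box_hex_grid, boundary_hex_faces, hexes_to_tets

# ---------------------------------------------------------------------------
# mesh builders
# ---------------------------------------------------------------------------


def build_cube_mesh(edge: float = 1.0, divisions: int = 2) -> LabeledMesh:
    """Tet-meshed cube with boundary nodes recorded in node set 'boundary'."""
    nodes0, hexes, _ = box_hex_grid((edge, edge, edge), (divisions,) * 3)
    nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
    eps = 1e-9 * edge
    on_bnd = np.any((nodes < eps) | (nodes > edge - eps), axis=1)
    mesh = LabeledMesh(
        nodes=nodes,
        tets=tets,
        element_region=np.array(["bone"] * len(tets), dtype=object),
        node_sets={"boundary": np.flatnonzero(on_bnd)},
    )
    return mesh


def build_spherical_shell(
    r_inner: float, r_outer: float, n_panel: int, n_radial: int
) -> LabeledMesh:
    """Conforming tet mesh of a full spherical shell via a cubed sphere.

    The six cube panels share nodes exactly (deduplication on the integer
    parameter lattice), and the centroid subdivision keeps the panel seams
    conforming.  Facet labels: ``inner`` and ``outer``.  Node sets
    ``axis_px``, ``axis_mx``, ``axis_py`` hold the nodes lying on the +x, -x
    and +y axes (used for minimal rigid-body constraints that are compatible
    with a purely radial field).
    """
    if n_panel % 2 != 0:
        raise ValueError("n_panel must be even so that axis nodes exist")
    # lattice points on cube surface, coordinates in {-n..n} with one = +/-n
    n = n_panel
    key_to_id = {}
    cube_pts = []

    def surf_id(p):
        fid = key_to_id.get(p)
        if fid is None:
            fid = len(cube_pts)
            key_to_id[p] = fid
            cube_pts.append(p)
        return fid

    panels = []  # list of (n+1, n+1) arrays of surface ids
    axes_defs = [
        (0, 1),  # +x: fixed axis 0 at +n
        (0, -1),
        (1, 1),
        (1, -1),
        (2, 1),
        (2, -1),
    ]
    for ax, sgn in axes_defs:
        grid = np.empty((n + 1, n + 1), dtype=np.int64)
        for i in range(n + 1):
            for j in range(n + 1):
                uv = [-n + 2 * i, -n + 2 * j]
                p = [0, 0, 0]
                p[ax] = sgn * n
                others = [a for a in range(3) if a != ax]
                p[others[0]], p[others[1]] = uv
                grid[i, j] = surf_id(tuple(p))
        panels.append((grid, ax, sgn))

    dirs = np.asarray(cube_pts, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.linspace(r_inner, r_outer, n_radial + 1)
    # nodes: layer-major
    nsurf = len(dirs)
    nodes0 = (radii[:, None, None] * dirs[None, :, :]).reshape(-1, 3)

    hexes = []
    for grid, ax, sgn in panels:
        for l in range(n_radial):
            base0 = l * nsurf
            base1 = (l + 1) * nsurf
            for i in range(n):
                for j in range(n):
                    quad = (grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1])
                    hexes.append(
                        [
                            base0 + quad[0],
                            base0 + quad[1],
                            base0 + quad[2],
                            base0 + quad[3],
                            base1 + quad[0],
                            base1 + quad[1],
                            base1 + quad[2],
                            base1 + quad[3],
                        ]
                    )
    hexes = np.asarray(hexes, dtype=np.int64)
    nodes, tets, tet_hex, tet_face = hexes_to_tets(nodes0, hexes)

    facets, owners = [], []
    tris, own = _boundary_tris(tets)
    cent_r = np.linalg.norm(nodes[tris].mean(axis=1), axis=1)
    labels = np.where(cent_r < 0.5 * (r_inner + r_outer), "inner", "outer")

    tol = 1e-9 * r_outer
    on_px = np.flatnonzero(
        (np.abs(nodes0[:, 1]) < tol) & (np.abs(nodes0[:, 2]) < tol) & (nodes0[:, 0] > 0)
    )
    on_mx = np.flatnonzero(
        (np.abs(nodes0[:, 1]) < tol) & (np.abs(nodes0[:, 2]) < tol) & (nodes0[:, 0] < 0)
    )
    on_py = np.flatnonzero(
        (np.abs(nodes0[:, 0]) < tol) & (np.abs(nodes0[:, 2]) < tol) & (nodes0[:, 1] > 0)
    )
    mesh = LabeledMesh(
        nodes=nodes,
        tets=tets,
        element_region=np.array(["bone"] * len(tets), dtype=object),
        facets=tris,
        facet_labels=labels.astype(object),
        node_sets={"axis_px": on_px, "axis_mx": on_mx, "axis_py": on_py},
    )
    return mesh


def _boundary_tris(tets):
    from .mesh import extract_boundary_triangles

    return extract_boundary_triangles(tets)


def build_beam_mesh(length, width, height, divisions) -> LabeledMesh:
    """Cantilever prism along +y; root face at y=0, tip face at y=length.

    Node sets ``root`` and ``tip``; facet label ``tip`` on the free end.
    """
    nx, ny, nz = divisions
    nodes0, hexes, _ = box_hex_grid((width, length, height), (nx, ny, nz))
    nodes0 = nodes0 - np.array([width / 2, 0.0, height / 2])
    nodes, tets, _, _ = hexes_to_tets(nodes0, hexes)
    eps = 1e-9 * length
    root = np.flatnonzero(np.abs(nodes[:, 1]) < eps)
    tipn = np.flatnonzero(np.abs(nodes[:, 1] - length) < eps)
    tris, _ = _boundary_tris(tets)
    tip_tris = np.all(np.abs(nodes[tris][:, :, 1] - length) < eps, axis=1)
    mesh = LabeledMesh(
        nodes=nodes,
        tets=tets,
        element_region=np.array(["bone"] * len(tets), dtype=object),
        facets=tris[tip_tris],
        facet_labels=np.array(["tip"] * int(tip_tris.sum()), dtype=object),
        node_sets={"root": root, "tip": tipn},
    )
    return mesh


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def lame_radial_displacement(r, r_inner, r_outer, pressure, E, nu):
    """Radial displacement of a thick-walled sphere under internal pressure."""
    r = np.asarray(r, dtype=float)
    c = pressure * r_inner**3 / (E * (r_outer**3 - r_inner**3))
    return c * ((1 - 2 * nu) * r + (1 + nu) * r_outer**3 / (2 * r**2))


def timoshenko_tip_deflection(P, L, E, nu, width, height):
    """Shear-corrected tip deflection of an end-loaded cantilever."""
    I = width * height**3 / 12.0
    A = width * height
    G = E / (2 * (1 + nu))
    kappa = 10.0 * (1 + nu) / (12.0 + 11.0 * nu)  # rectangular section
    return P * L**3 / (3 * E * I) + P * L / (kappa * G * A)


# ---------------------------------------------------------------------------
# benchmark drivers
# ---------------------------------------------------------------------------


def run_patch_test(divisions: int = 2, material: fem.Material | None = None):
    """Affine field u = A x + b imposed on the cube boundary.

    Returns the maximum relative element-strain error against the exact
    constant strain of the imposed field.
    """
    material = material or fem.Material(6000.0, 0.27)
    mesh = build_cube_mesh(1.0, divisions)
    A = np.array([[3.0, 1.2, -0.4], [0.7, -2.0, 0.5], [-0.3, 0.8, 1.5]]) * 1e-4
    b = np.array([1.0, -2.0, 0.5]) * 1e-4
    exact = 0.5 * (A + A.T)
    exact_voigt = np.array(
        [exact[0, 0], exact[1, 1], exact[2, 2], exact[0, 1], exact[0, 2], exact[1, 2]]
    )

    system = fem.assemble(mesh, {"bone": material})
    bnd = mesh.node_sets["boundary"]
    ub = mesh.nodes[bnd] @ A.T + b
    fem.apply_dirichlet(system, bnd, ("x", "y", "z"), ub)
    U, info = fem.solve(system)
    strain = fem.recover_strain(mesh, U)
    err = np.abs(strain.element_strain - exact_voigt[None, :]).max()
    return err / np.abs(exact_voigt).max(), info


def run_lame_sphere(
    n_panel: int,
    n_radial: int,
    r_inner: float = 50.0,
    r_outer: float = 70.0,
    pressure: float = 0.1,
    material: fem.Material | None = None,
):
    """Solve the pressurized shell; return (relative mid-wall error, n_elements)."""
    material = material or fem.Material(6000.0, 0.27)
    mesh = build_spherical_shell(r_inner, r_outer, n_panel, n_radial)
    system = fem.assemble(mesh, {"bone": material})
    forces = fem.pressure_loads(mesh, "inner", pressure)
    fem.add_nodal_forces(system, forces)
    # minimal 6-DOF constraints compatible with a radial field
    fem.apply_dirichlet(system, mesh.node_sets["axis_px"], ("y", "z"))
    fem.apply_dirichlet(system, mesh.node_sets["axis_mx"], ("y", "z"))
    fem.apply_dirichlet(system, mesh.node_sets["axis_py"], ("x", "z"))
    U, info = fem.solve(system)

    r = np.linalg.norm(mesh.nodes, axis=1)
    r_mid = 0.5 * (r_inner + r_outer)
    dr = 0.25 * (r_outer - r_inner)
    sel = np.abs(r - r_mid) < dr
    u_r = np.einsum("ij,ij->i", U[sel], mesh.nodes[sel] / r[sel, None])
    exact = lame_radial_displacement(
        r[sel], r_inner, r_outer, pressure, material.youngs_modulus, material.poisson_ratio
    )
    err = np.abs(np.mean(u_r / exact) - 1.0)
    return err, mesh.n_elements, info


def run_cantilever(
    divisions=(6, 40, 6),
    length: float = 80.0,
    width: float = 8.0,
    height: float = 8.0,
    load: float = 1.0,
    material: fem.Material | None = None,
):
    """End-loaded cantilever; return (relative tip-deflection error, n_elements)."""
    material = material or fem.Material(6000.0, 0.3)
    mesh = build_beam_mesh(length, width, height, divisions)
    system = fem.assemble(mesh, {"bone": material})
    forces = fem.point_loads_on_patch(mesh, "tip", np.array([0.0, 0.0, -load]))
    fem.add_nodal_forces(system, forces)
    fem.apply_dirichlet(system, mesh.node_sets["root"], ("x", "y", "z"))
    U, info = fem.solve(system)
    tip_defl = -U[mesh.node_sets["tip"], 2].mean()
    exact = timoshenko_tip_deflection(
        load, length, material.youngs_modulus, material.poisson_ratio, width, height
    )
    return abs(tip_defl / exact - 1.0), mesh.n_elements, info
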