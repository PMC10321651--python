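"""Linear isotropic elastostatics on 4-node (constant-strain) tetrahedra.

Units are mm / N / MPa throughout.  Strain tensors use the *tensor* shear
convention (eps_xy = gamma_xy / 2); reported microstrain values can be
converted to engineering shear for comparison tables via
:func:`calvaria.analytics` flags.  Components are ordered
(xx, yy, zz, xy, xz, yz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")

#: floor below which a tet is treated as degenerate, mm^3
DEGENERATE_VOLUME = 1e-12


class FemError(RuntimeError):
    pass


class SingularSystemError(FemError):
    pass


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material (E in MPa)."""

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self):
        if not self.youngs_modulus > 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")

    @property
    def lame(self):
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu

    def d_matrix(self) -> np.ndarray:
        """6x6 constitutive matrix in engineering-Voigt form."""
        lam, mu = self.lame
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


@dataclass
class LinearSystem:
    """Assembled global stiffness + loads + homogeneous/inhomogeneous BCs."""

    stiffness: sp.csr_matrix
    load_vector: np.ndarray
    n_nodes: int
    constrained_dofs: dict = field(default_factory=dict)  # dof index -> value

    def constrain(self, node_ids, axes, values=0.0):
        axmap = {"x": 0, "y": 1, "z": 2}
        node_ids = np.atleast_1d(np.asarray(node_ids, dtype=np.int64))
        if node_ids.size == 0:
            raise FemError("empty node set in Dirichlet constraint")
        if not axes:
            raise FemError("no axes given in Dirichlet constraint")
        values = np.broadcast_to(np.asarray(values, dtype=float), (node_ids.size, 3))
        for ax in axes:
            a = axmap[ax]
            for n, v in zip(node_ids, values[:, a]):
                self.constrained_dofs[3 * int(n) + a] = float(v)


@dataclass
class StrainField:
    """Element/nodal symmetric strain tensors (tensor-shear convention)."""

    element_strain: np.ndarray  # (m, 6)
    node_strain: np.ndarray  # (n, 6)
    principal: np.ndarray  # (n, 3), eps1 >= eps2 >= eps3

    @staticmethod
    def principal_of(tensors: np.ndarray) -> np.ndarray:
        full = voigt_to_tensor(tensors)
        vals = np.linalg.eigvalsh(full)  # ascending
        return vals[:, ::-1]


@dataclass
class StressField:
    element_stress: np.ndarray  # (m, 6) MPa
    node_stress: np.ndarray  # (n, 6) MPa
    von_mises: np.ndarray  # (n,)
    tresca: np.ndarray  # (n,)
    element_von_mises: np.ndarray  # (m,)


def voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    """(k, 6) tensor-convention Voigt -> (k, 3, 3) symmetric matrices."""
    v = np.atleast_2d(v)
    T = np.empty((len(v), 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = v[:, 0], v[:, 1], v[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = v[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = v[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = v[:, 5]
    return T


def _shape_gradients(coords: np.ndarray, check=True):
    """Shape-function gradients and signed volumes for a batch of tets.

    coords: (m, 4, 3).  Returns (grads (m, 4, 3), volumes (m,)).
    """
    v1 = coords[:, 1] - coords[:, 0]
    v2 = coords[:, 2] - coords[:, 0]
    v3 = coords[:, 3] - coords[:, 0]
    J = np.stack([v1, v2, v3], axis=1)  # rows are edge vectors
    vol = np.linalg.det(J) / 6.0
    if check and np.any(np.abs(vol) <= DEGENERATE_VOLUME):
        bad = int(np.argmin(np.abs(vol)))
        raise FemError(f"degenerate element {bad} (volume {vol[bad]:.3e} mm^3)")
    Jinv = np.linalg.inv(J)
    # dN_i/dx for i=1..3 are columns of Jinv; N0 = 1 - sum
    g123 = np.swapaxes(Jinv, 1, 2)  # (m, 3ref, 3xyz) -> rows per ref coord
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Engineering-Voigt strain-displacement matrices, (m, 6, 12)."""
    m = len(grads)
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 1] = gz
        B[:, 5, c + 2] = gy
    return B


def element_stiffness(tet_coords: np.ndarray, material: Material) -> np.ndarray:
    """12x12 stiffness of a single constant-strain tetrahedron.

    Node orderings of either orientation are accepted (the stiffness uses
    |V|, so a mirrored ordering yields the same matrix spectrum).
    """
    coords = np.asarray(tet_coords, dtype=float).reshape(1, 4, 3)
    grads, vol = _shape_gradients(coords)
    B = _b_matrices(grads)[0]
    return abs(vol[0]) * B.T @ material.d_matrix() @ B


def assemble(mesh, materials: dict) -> LinearSystem:
    """Assemble the global stiffness for a labeled mesh.

    materials: region label -> :class:`Material`.  Every region present in
    the mesh must have an entry.
    """
    regions = set(mesh.element_region)
    missing = regions - set(materials)
    if missing:
        raise FemError(f"missing material for regions: {sorted(missing)}")

    coords = mesh.nodes[mesh.tets]
    grads, vol = _shape_gradients(coords)
    if np.any(vol <= DEGENERATE_VOLUME):
        bad = int(np.argmin(vol))
        raise FemError(f"degenerate element {bad} (volume {vol[bad]:.3e} mm^3)")
    B = _b_matrices(grads)

    m = mesh.n_elements
    Ke = np.empty((m, 12, 12))
    for region in sorted(regions):
        els = mesh.elements_of_region(region)
        D = materials[region].d_matrix()
        BD = np.einsum("eji,jk->eik", B[els], D)  # (e, 12, 6)
        Ke[els] = np.einsum("eik,ekl,e->eil", BD, B[els], vol[els])

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return LinearSystem(stiffness=K, load_vector=np.zeros(ndof), n_nodes=mesh.n_nodes)


def apply_dirichlet(system: LinearSystem, node_ids, axes, values=0.0) -> LinearSystem:
    """Prescribe displacement components on a node set (default 0)."""
    system.constrain(node_ids, axes, values)
    return system


def add_nodal_forces(system: LinearSystem, forces: np.ndarray):
    """Accumulate an (n, 3) nodal force array into the load vector."""
    system.load_vector += np.asarray(forces, dtype=float).ravel()
    return system


def point_loads_on_patch(mesh, facet_label: str, total_force) -> np.ndarray:
    """Distribute a resultant over a labeled facet patch by tributary area.

    Each triangle's area is split equally to its three nodes; nodal force is
    ``total_force * (tributary area / patch area)``, so the nodal forces sum
    to the resultant exactly and all act along the same direction.
    """
    fids = mesh.facets_of_label(facet_label)
    if fids.size == 0:
        raise FemError(f"facet patch {facet_label!r} is empty or missing")
    tris = mesh.facets[fids]
    areas, _ = _areas(mesh.nodes, tris)
    weights = np.zeros(mesh.n_nodes)
    np.add.at(weights, tris.ravel(), np.repeat(areas / 3.0, 3))
    weights /= weights.sum()
    return weights[:, None] * np.asarray(total_force, dtype=float)[None, :]


def _areas(nodes, tris):
    p = nodes[tris]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm = np.linalg.norm(cr, axis=1)
    return 0.5 * nrm, cr / nrm[:, None]


def pressure_loads(mesh, facet_label: str, pressure: float) -> np.ndarray:
    """Nodal forces from uniform pressure (MPa) on an outward-oriented patch.

    Traction is ``-p * n_outward``: positive pressure pushes on the surface,
    negative pressure (suction) pulls along the outward normal.  Each facet's
    force is split equally among its three nodes.
    """
    fids = mesh.facets_of_label(facet_label)
    if fids.size == 0:
        raise FemError(f"facet patch {facet_label!r} is empty or missing")
    tris = mesh.facets[fids]
    p = mesh.nodes[tris]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2 * area * n_out
    facet_force = -pressure * 0.5 * cr
    forces = np.zeros((mesh.n_nodes, 3))
    per_node = np.repeat(facet_force / 3.0, 3, axis=0)
    np.add.at(forces, tris.ravel(), per_node)
    return forces


def solve(system: LinearSystem, method: str = "direct"):
    """Solve the constrained system.

    method: ``direct`` (sparse LU, default) or ``cg`` (conjugate gradients
    with relative tolerance 1e-10); both must meet the 1e-8 residual
    contract.  Returns ``(U, info)`` where ``U`` is (n, 3) displacements
    (mm) and ``info`` carries reactions at constrained DOFs, the relative
    residual and global force balance.
    """
    ndof = 3 * system.n_nodes
    K, f = system.stiffness, system.load_vector
    con = np.fromiter(sorted(system.constrained_dofs), dtype=np.int64)
    if con.size < 6:
        raise SingularSystemError(
            "fewer than 6 constrained DOFs: rigid-body translations/rotations remain"
        )
    con_vals = np.array([system.constrained_dofs[d] for d in con])
    free = np.setdiff1d(np.arange(ndof), con, assume_unique=True)

    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, con] @ con_vals
    if method == "cg":
        u_free, cg_info = spla.cg(Kff, rhs, rtol=1e-10, maxiter=20 * len(rhs))
        if cg_info != 0:
            raise SingularSystemError(f"CG failed to converge (info={cg_info})")
    elif method == "direct":
        try:
            lu = spla.splu(Kff)
            u_free = lu.solve(rhs)
        except RuntimeError as exc:  # singular factorization
            raise SingularSystemError(f"stiffness factorization failed: {exc}") from exc
    else:
        raise ValueError(f"unknown solver method {method!r}")
    if not np.all(np.isfinite(u_free)):
        raise SingularSystemError("non-finite solution: remaining rigid-body modes")

    U = np.empty(ndof)
    U[free] = u_free
    U[con] = con_vals

    rhs_norm = np.linalg.norm(rhs)
    residual = np.linalg.norm(Kff @ u_free - rhs) / (rhs_norm if rhs_norm > 0 else 1.0)
    if residual > 1e-8:
        raise SingularSystemError(f"solver residual {residual:.2e} exceeds 1e-8")

    full_r = K @ U - f
    reactions = np.zeros(ndof)
    reactions[con] = full_r[con]
    applied_total = f.reshape(-1, 3).sum(axis=0)
    reaction_total = reactions.reshape(-1, 3).sum(axis=0)
    info = {
        "residual": residual,
        "reactions": reactions.reshape(-1, 3),
        "applied_total": applied_total,
        "reaction_total": reaction_total,
        "n_constrained": int(con.size),
    }
    return U.reshape(-1, 3), info


class CachedSolver:
    """Re-usable assembly + factorization for one mesh/material pairing.

    Factorizations are cached per constraint pattern, so load cases sharing
    boundary conditions (e.g. the per-muscle decomposition) cost one
    factorization and cheap back-substitutions.
    """

    def __init__(self, mesh, materials: dict):
        self.mesh = mesh
        base = assemble(mesh, materials)
        self.K = base.stiffness
        self.ndof = 3 * mesh.n_nodes
        self._cache = {}

    def solve(self, forces: np.ndarray, dirichlet):
        """dirichlet: list of (node index array, axes tuple)."""
        system = LinearSystem(self.K, np.zeros(self.ndof), self.mesh.n_nodes)
        for node_ids, axes in dirichlet:
            system.constrain(node_ids, axes)
        con = np.fromiter(sorted(system.constrained_dofs), dtype=np.int64)
        key = con.tobytes()
        if key not in self._cache:
            free = np.setdiff1d(np.arange(self.ndof), con, assume_unique=True)
            lu = spla.splu(self.K[free][:, free].tocsc())
            self._cache[key] = (free, con, lu)
        free, con, lu = self._cache[key]
        f = np.asarray(forces, dtype=float).ravel()
        u_free = lu.solve(f[free])
        U = np.zeros(self.ndof)
        U[free] = u_free
        rhs_norm = np.linalg.norm(f[free])
        residual = np.linalg.norm(self.K[free][:, free] @ u_free - f[free]) / (
            rhs_norm if rhs_norm > 0 else 1.0
        )
        if not np.all(np.isfinite(u_free)) or residual > 1e-8:
            raise SingularSystemError(f"cached solve residual {residual:.2e}")
        full_r = self.K @ U - f
        reactions = np.zeros(self.ndof)
        reactions[con] = full_r[con]
        info = {
            "residual": residual,
            "reactions": reactions.reshape(-1, 3),
            "applied_total": f.reshape(-1, 3).sum(axis=0),
            "reaction_total": reactions.reshape(-1, 3).sum(axis=0),
            "n_constrained": int(con.size),
        }
        return U.reshape(-1, 3), info


def recover_strain(mesh, U: np.ndarray) -> StrainField:
    """Constant element strains and volume-weighted nodal recovery."""
    U = np.asarray(U, dtype=float).reshape(-1, 3)
    coords = mesh.nodes[mesh.tets]
    grads, vol = _shape_gradients(coords)
    ue = U[mesh.tets]  # (m, 4, 3)
    # tensor strain: eps_ij = 0.5 * (du_i/dx_j + du_j/dx_i)
    gradu = np.einsum("maj,mai->mij", grads, ue)  # (m, 3, 3) du_i/dx_j
    eps = 0.5 * (gradu + np.swapaxes(gradu, 1, 2))
    element = np.column_stack(
        [eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2], eps[:, 0, 1], eps[:, 0, 2], eps[:, 1, 2]]
    )
    node = _volume_weighted_nodal(mesh, element, vol)
    principal = StrainField.principal_of(node)
    return StrainField(element_strain=element, node_strain=node, principal=principal)


def _volume_weighted_nodal(mesh, element_values: np.ndarray, vol: np.ndarray) -> np.ndarray:
    n = mesh.n_nodes
    k = element_values.shape[1]
    acc = np.zeros((n, k))
    wsum = np.zeros(n)
    ids = mesh.tets.ravel()
    np.add.at(acc, ids, np.repeat(element_values * vol[:, None], 4, axis=0))
    np.add.at(wsum, ids, np.repeat(vol, 4))
    return acc / wsum[:, None]


def stress_from_strain(strain: StrainField, mesh, materials: dict) -> StressField:
    """Isotropic Hooke's law per region + von Mises / Tresca invariants."""
    m = mesh.n_elements
    sig = np.empty((m, 6))
    eps = strain.element_strain
    for region in sorted(set(mesh.element_region)):
        els = mesh.elements_of_region(region)
        lam, mu = materials[region].lame
        tr = eps[els, :3].sum(axis=1)
        sig[els, :3] = lam * tr[:, None] + 2 * mu * eps[els, :3]
        sig[els, 3:] = 2 * mu * eps[els, 3:]
    vol = mesh.volumes()
    node_sig = _volume_weighted_nodal(mesh, sig, vol)
    vm_n, tresca_n = stress_invariants(node_sig)
    vm_e, _ = stress_invariants(sig)
    return StressField(
        element_stress=sig,
        node_stress=node_sig,
        von_mises=vm_n,
        tresca=tresca_n,
        element_von_mises=vm_e,
    )


def stress_invariants(sig_voigt: np.ndarray):
    """(von Mises, Tresca) from (k, 6) stress tensors."""
    s = np.atleast_2d(sig_voigt)
    sxx, syy, szz, sxy, sxz, syz = (s[:, i] for i in range(6))
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + sxz**2 + syz**2)
    )
    principal = StrainField.principal_of(s)
    tresca = principal[:, 0] - principal[:, 2]
    return vm, tresca
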