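"""Labeled tetrahedral mesh container and structured hex-to-tet utilities.

The pipeline frame follows craniometric convention: +x superior, +y anterior,
+z toward the patient's left, origin at the inter-condylar (TMJ) midpoint.
All lengths are millimetres.

Tetrahedra follow a positive signed-volume node-ordering convention
(``det([p1-p0, p2-p0, p3-p0]) > 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

import numpy as np

# Canonical region vocabulary.  Order matters: it fixes the integer codes used
# by the VTK writer, so it must never be reordered, only appended to.
REGION_LABELS = (
    "bone",
    "metopic",
    "sagittal",
    "coronal_L",
    "coronal_R",
    "lambdoid_L",
    "lambdoid_R",
    "squamous_L",
    "squamous_R",
    "nasofrontal",
    "anterior_fontanelle",
    "posterior_fontanelle",
    "synchondrosis",
    "palate_bone",
    "face_bone",
)

SUTURE_REGIONS = (
    "metopic",
    "sagittal",
    "coronal_L",
    "coronal_R",
    "lambdoid_L",
    "lambdoid_R",
    "squamous_L",
    "squamous_R",
    "nasofrontal",
    "anterior_fontanelle",
    "posterior_fontanelle",
    "synchondrosis",
)

#: node sets every generated calvarium must carry
REQUIRED_NODE_SETS = (
    "tmj_L",
    "tmj_R",
    "bite_R_molar1",
    "bite_R_molar2",
    "bite_R_lateral_incisor",
    "latch_midline",
    "foramen_magnum",
    "nasion",
    "glabella",
    "bregma",
)


class MeshError(ValueError):
    """Raised for inconsistent or degenerate mesh data."""


@dataclass
class LabeledMesh:
    """Conforming tetrahedral mesh with per-element region labels.

    Attributes
    ----------
    nodes : (n, 3) float array, mm
    tets : (m, 4) int array, positive signed volume ordering
    element_region : (m,) array of region label strings
    facets : (f, 3) int array
        Oriented boundary triangles (outward normals) that carry a label.
    facet_labels : (f,) array of strings
        e.g. ``ectocranial``, ``endocranial``, ``palate``, ``alveolar``,
        ``attachment:<muscle>:<side>``.
    node_sets : dict of name -> int array (landmarks, constraint patches,
        analysis regions).
    metadata : free-form provenance (generator parameters etc.).
    """

    nodes: np.ndarray
    tets: np.ndarray
    element_region: np.ndarray
    facets: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    facet_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    node_sets: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.element_region = np.asarray(self.element_region, dtype=object)
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64)
        self.facet_labels = np.asarray(self.facet_labels, dtype=object)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be (m, 4)")
        if len(self.element_region) != len(self.tets):
            raise MeshError("element_region length must match tets")
        if len(self.facet_labels) != len(self.facets):
            raise MeshError("facet_labels length must match facets")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def elements_of_region(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.element_region == region)

    def facets_of_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.facet_labels == label)

    def region_node_ids(self, region: str) -> np.ndarray:
        """Nodes incident to at least one element of ``region``."""
        els = self.elements_of_region(region)
        return np.unique(self.tets[els])

    def surface_node_ids(self, labels=("ectocranial", "endocranial")) -> np.ndarray:
        mask = np.isin(self.facet_labels, labels)
        return np.unique(self.facets[mask])

    def content_hash(self) -> str:
        """SHA-256 over coordinates, connectivity and labels (determinism checks)."""
        h = hashlib.sha256()
        h.update(self.nodes.tobytes())
        h.update(self.tets.tobytes())
        h.update("|".join(self.element_region).encode())
        h.update(self.facets.tobytes())
        h.update("|".join(self.facet_labels).encode())
        for name in sorted(self.node_sets):
            h.update(name.encode())
            h.update(np.asarray(self.node_sets[name], dtype=np.int64).tobytes())
        return h.hexdigest()


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes, mm^3 (positive under the ordering convention)."""
    p = nodes[tets]
    return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


def triangle_areas_normals(nodes: np.ndarray, tris: np.ndarray):
    """(areas, unit normals) of triangles, normal by right-hand rule."""
    p = nodes[tris]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm = np.linalg.norm(cr, axis=1)
    areas = 0.5 * nrm
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = cr / nrm[:, None]
    return areas, unit


def min_dihedral_angles(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Minimum interior dihedral angle per tet, degrees."""
    p = nodes[tets]
    # inward face normals: face i is opposite vertex i
    faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    normals = []
    for (a, b, c) in faces:
        n = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        normals.append(n)
    mins = np.full(len(tets), np.inf)
    for i in range(4):
        for j in range(i + 1, 4):
            # dihedral along shared edge: angle between faces = pi - angle(normals)
            c = np.einsum("ij,ij->i", normals[i], normals[j])
            ang = np.pi - np.arccos(np.clip(c, -1.0, 1.0))
            mins = np.minimum(mins, ang)
    return np.degrees(mins)


# ---------------------------------------------------------------------------
# structured hex grids -> conforming tets
# ---------------------------------------------------------------------------

# VTK hexahedron local faces (ordered quads).  Bottom 0-3 CCW, top 4-7.
_HEX_FACES = (
    (0, 3, 2, 1),  # bottom (k-)
    (4, 5, 6, 7),  # top (k+)
    (0, 1, 5, 4),  # j-
    (2, 3, 7, 6),  # j+
    (1, 2, 6, 5),  # i+
    (0, 4, 7, 3),  # i-
)


def hexes_to_tets(nodes: np.ndarray, hexes: np.ndarray):
    """Subdivide a node-shared hexahedral mesh into conforming tetrahedra.

    Each hex is split into 24 tets through its six face centroids and its body
    centroid.  Because a shared quad face produces the same centroid node and
    the same four edge-triangles on either side, the result is conforming
    across *any* pair of node-sharing hexes — including seams between
    differently-oriented structured patches — and the subdivision commutes
    with mirror reflection.

    Returns
    -------
    all_nodes : (n', 3) array (original nodes first, then face centroids,
        then body centroids)
    tets : (24*H, 4) int array, positive volumes
    tet_hex : (24*H,) index of the parent hex
    tet_face : (24*H,) local face index 0..5 of the parent hex face the tet
        is based on (its outward triangle is ``tets[t, [0, 1, 2]`` minus the
        body centroid).
    """
    nodes = np.asarray(nodes, dtype=np.float64)
    hexes = np.asarray(hexes, dtype=np.int64)
    nh = len(hexes)
    n0 = len(nodes)

    # dedupe face centroids by sorted node key
    face_key_to_id = {}
    face_centroid_coords = []
    face_ids = np.empty((nh, 6), dtype=np.int64)
    for f, loc in enumerate(_HEX_FACES):
        quads = hexes[:, loc]  # (nh, 4)
        keys = np.sort(quads, axis=1)
        for h in range(nh):
            key = tuple(keys[h])
            fid = face_key_to_id.get(key)
            if fid is None:
                fid = n0 + len(face_centroid_coords)
                face_key_to_id[key] = fid
                face_centroid_coords.append(nodes[quads[h]].mean(axis=0))
            face_ids[h, f] = fid

    body_ids = n0 + len(face_centroid_coords) + np.arange(nh)
    body_coords = nodes[hexes].mean(axis=1)
    all_nodes = np.vstack([nodes, np.asarray(face_centroid_coords).reshape(-1, 3), body_coords])

    tets = np.empty((nh * 24, 4), dtype=np.int64)
    tet_hex = np.repeat(np.arange(nh), 24)
    tet_face = np.tile(np.repeat(np.arange(6), 4), nh)
    t = 0
    for h in range(nh):
        bc = body_ids[h]
        for f, loc in enumerate(_HEX_FACES):
            q = hexes[h, list(loc)]
            fc = face_ids[h, f]
            for e in range(4):
                tets[t] = (q[e], q[(e + 1) % 4], fc, bc)
                t += 1

    vols = tet_volumes(all_nodes, tets)
    neg = vols < 0
    tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()
    return all_nodes, tets, tet_hex, tet_face


def boundary_hex_faces(hexes: np.ndarray):
    """(hex index, local face index) pairs of unshared hex faces."""
    counts = {}
    for f, loc in enumerate(_HEX_FACES):
        quads = np.sort(hexes[:, loc], axis=1)
        for h in range(len(hexes)):
            key = tuple(quads[h])
            counts.setdefault(key, []).append((h, f))
    return [pairs[0] for pairs in counts.values() if len(pairs) == 1]


def extract_boundary_triangles(tets: np.ndarray):
    """Outward-oriented boundary triangles of a tet mesh with owner tets.

    A face of a positively-ordered tet ``(a, b, c, d)`` listed as in
    ``faces`` below has its right-hand normal pointing away from the
    remaining vertex, i.e. outward when the face lies on the boundary.
    """
    faces = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ]
    )
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key_sorted = key[order]
    uniq_mask = np.ones(len(key_sorted), dtype=bool)
    dup = np.all(key_sorted[1:] == key_sorted[:-1], axis=1)
    uniq_mask[1:][dup] = False
    uniq_mask[:-1][dup] = False
    sel = order[uniq_mask]
    return faces[sel], owner[sel]


def box_hex_grid(lengths, divisions, origin=(0.0, 0.0, 0.0)):
    """Structured hex grid of an axis-aligned box.

    Returns (nodes, hexes, node_index) where ``node_index[i, j, k]`` maps grid
    coordinates to node ids.
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0.0, lx, nx + 1) + origin[0]
    ys = np.linspace(0.0, ly, ny + 1) + origin[1]
    zs = np.linspace(0.0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    hexes = np.empty((nx * ny * nz, 8), dtype=np.int64)
    h = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes[h] = (
                    idx[i, j, k],
                    idx[i + 1, j, k],
                    idx[i + 1, j + 1, k],
                    idx[i, j + 1, k],
                    idx[i, j, k + 1],
                    idx[i + 1, j, k + 1],
                    idx[i + 1, j + 1, k + 1],
                    idx[i, j + 1, k + 1],
                )
                h += 1
    return nodes, hexes, idx
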