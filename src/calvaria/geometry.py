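"""Parametric synthetic infant calvarium with labeled sutures and landmarks.

The geometry is a deliberate idealization: the cranial vault is a thickened
ellipsoidal shell, the face a tapered block hanging from the anterior vault
rim, with a flat hard-palate plate and an alveolar margin.  Sutures are
full-thickness strips of elements following great-arc paths on the vault
(metopic from nasion to bregma in the midline, sagittal from bregma to the
posterior fontanelle, paired coronal / lambdoid / squamous arcs laterally),
plus a nasofrontal band at the anterior rim, fontanelle patches, and a
basicranial synchondrosis band around the foramen magnum.  There are no
orbits, sinuses or tooth crypts.

Frame: +x superior, +y anterior, +z left; origin at the inter-condylar (TMJ)
midpoint; lengths in mm.  The mesh is conforming everywhere — sutures, bone,
and the face block share interface nodes — which realizes bonded (tie-type)
suture interfaces exactly.

The vault is meshed from a single structured grid mapped square -> disk
(concentric/area-preserving map) -> ellipsoid dome, so meshing is fully
deterministic and exactly mirror-symmetric in node positions about z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .mesh import (
    LabeledMesh,
    MeshError,
    REQUIRED_NODE_SETS,
    boundary_hex_faces,
    hexes_to_tets,
)

MUSCLES = (
    "deep_masseter",
    "superficial_masseter",
    "anterior_temporalis",
    "posterior_temporalis",
    "medial_pterygoid",
)

PHYSIOLOGIC_INTERFRONTAL_ANGLE = 135.0

# angular layout of the vault (degrees); see docs/methods.md
_RIM_ANTERIOR = 72.0  # colatitude of the anterior rim (nasion level)
# the lateral/posterior rim reaches well below the equator so the shell curves
# inward into a partial basicranial bowl; this gives the lower vault the ring
# stiffness of the skull base (petrous/occipital anchoring), which carries the
# masticatory pull into the TMJ instead of leaving the squama free-hanging
_RIM_LATERAL = 124.0
_RIM_POSTERIOR = 130.0
_FONTANELLE_ANT_RADIUS = 12.0  # mm, anterior fontanelle patch radius
_FONTANELLE_POST_RADIUS = 8.0  # mm
_PF_COLAT = 78.0  # posterior fontanelle (lambda) colatitude on the midline
_CORONAL_PSI = 72.0  # coronal suture meridian
_SQUAMOUS_COLAT = 95.0  # squamous arc colatitude
_TMJ_PSI = 95.0  # TMJ patch azimuth on the lateral rim


class GeometryError(MeshError):
    pass


@dataclass(frozen=True)
class CalvariumParams:
    """Parameters of the synthetic calvarium generator.

    vault_semiaxes : (x, y, z) outer semiaxes of the vault ellipsoid, mm.
    shell_thickness : vault shell thickness, mm.
    suture_width : width of suture strips, mm.
    metopic_closure_fraction : 0 = fully patent, 1 = fully fused.
    interfrontal_angle : degrees; 135 is the physiologic default, values
        near 100-105 produce the trigonocephalic (synostotic) taper.
    face_depth : vertical drop from nasion to the palate plate, mm.
    palate_dimensions : (width, depth) of the hard-palate plate, mm.
    target_edge_length : requested element edge length, mm.
    random_seed : recorded for provenance; generation is deterministic.
    landmark_overrides : optional landmark name -> coordinate, snapped to
        the nearest mesh node.
    """

    vault_semiaxes: tuple = (55.0, 70.0, 52.0)
    shell_thickness: float = 4.0
    suture_width: float = 7.0
    metopic_closure_fraction: float = 0.0
    interfrontal_angle: float = PHYSIOLOGIC_INTERFRONTAL_ANGLE
    face_depth: float = 36.0
    palate_dimensions: tuple = (32.0, 26.0)
    target_edge_length: float = 6.0
    random_seed: int = 0
    landmark_overrides: dict | None = None

    def validate(self):
        if any(s <= 0 for s in self.vault_semiaxes):
            raise GeometryError("vault semiaxes must be positive")
        for name in ("shell_thickness", "suture_width", "face_depth", "target_edge_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if any(d <= 0 for d in self.palate_dimensions):
            raise GeometryError("palate dimensions must be positive")
        if not 0.0 <= self.metopic_closure_fraction <= 1.0:
            raise GeometryError("metopic_closure_fraction must lie in [0, 1]")
        if not 60.0 < self.interfrontal_angle < 180.0:
            raise GeometryError("interfrontal_angle must lie in (60, 180) degrees")
        if self.suture_width < self.target_edge_length / 2:
            raise GeometryError(
                "suture_width must be >= target_edge_length/2 so sutures are "
                "resolvable by at least one element across"
            )


@dataclass(frozen=True)
class MuscleAttachment:
    """Cranial origin patch + mandibular insertion point of one muscle."""

    muscle: str
    side: str  # 'L' | 'R'
    origin_facets: str  # facet label of the origin patch
    insertion_centroid: np.ndarray = dataclass_field(default_factory=lambda: np.zeros(3))


# default mandibular insertion points, left side (+z); mm in the TMJ-origin
# frame.  The temporalis line of action hugs the lateral skull wall down to
# the coronoid process (near-vertical for the anterior fibres, strongly
# anterior for the posterior fibres); the masseters pull the zygomatic-arch
# band down and slightly posteriorly toward the angle/ramus; the medial
# pterygoid runs from the pterygoid region infero-latero-posteriorly to the
# medial mandibular angle.
_INSERTIONS_L = {
    "superficial_masseter": (-26.0, 10.0, 40.0),  # mandibular angle, lateral
    "deep_masseter": (-20.0, 6.0, 40.0),  # ramus, lateral
    "anterior_temporalis": (-6.0, 20.0, 44.0),  # coronoid process
    "posterior_temporalis": (-2.0, 28.0, 44.0),
    "medial_pterygoid": (-26.0, 8.0, 24.0),  # mandibular angle, medial
}


def square_to_disk(a: np.ndarray, b: np.ndarray):
    """Concentric (Shirley-Chiu) map of the square [-1,1]^2 onto the unit disk.

    Returns (radius, psi) with psi = atan2(q, p) the disk azimuth.  The map is
    bijective, keeps grid lines well-shaped, and commutes with reflections,
    which makes the vault mesh exactly mirror-symmetric.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    absa, absb = np.abs(a), np.abs(b)
    first = absa >= absb
    safe_a = np.where(a == 0, 1.0, a)
    safe_b = np.where(b == 0, 1.0, b)
    r = np.where(first, a, b)
    phi = np.where(
        first,
        (np.pi / 4) * (b / safe_a),
        (np.pi / 2) - (np.pi / 4) * (a / safe_b),
    )
    both_zero = (absa == 0) & (absb == 0)
    p = np.where(both_zero, 0.0, r * np.cos(phi))
    q = np.where(both_zero, 0.0, r * np.sin(phi))
    return np.abs(r), np.arctan2(q, p)


def _rim_colatitude(psi):
    """Direction-dependent vault-rim colatitude (deg); anterior rim is higher
    (the face attaches there), lateral/posterior rims reach below the equator."""
    c = np.cos(psi)
    ant = np.clip(c, 0.0, None)
    post = np.clip(-c, 0.0, None)
    return _RIM_LATERAL - (_RIM_LATERAL - _RIM_ANTERIOR) * ant + (_RIM_POSTERIOR - _RIM_LATERAL) * post


def _dome_point(colat, psi, semiaxes):
    ax, ay, az = semiaxes
    return np.stack(
        [
            ax * np.cos(colat),
            ay * np.sin(colat) * np.cos(psi),
            az * np.sin(colat) * np.sin(psi),
        ],
        axis=-1,
    )


def _dome_normal(colat, psi, semiaxes):
    ax, ay, az = semiaxes
    n = np.stack(
        [
            np.cos(colat) / ax,
            np.sin(colat) * np.cos(psi) / ay,
            np.sin(colat) * np.sin(psi) / az,
        ],
        axis=-1,
    )
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def build_calvarium(params: CalvariumParams = CalvariumParams()) -> LabeledMesh:
    """Generate the labeled calvarium mesh at the requested closure state."""
    params.validate()
    ax, ay, az = params.vault_semiaxes
    r_mean = float(np.mean(params.vault_semiaxes))
    edge = params.target_edge_length

    # --- structured vault grid ---------------------------------------------
    arc_diameter = 2.0 * np.radians(_RIM_LATERAL) * r_mean
    n_cells = max(16, int(round(arc_diameter / edge)))
    if n_cells % 2:
        n_cells += 1  # even cells -> odd node count -> exact midline/pole nodes
    N = n_cells + 1
    nt = max(2, int(round(params.shell_thickness / edge)))

    lin = np.linspace(-1.0, 1.0, N)
    A, B = np.meshgrid(lin, lin, indexing="ij")  # i: a (anterior at i=N-1), j: b (left at j=N-1)
    rdisk, psi = square_to_disk(A, B)
    colat = rdisk * np.radians(_rim_colatitude(psi))

    outer = _dome_point(colat, psi, params.vault_semiaxes)
    normal = _dome_normal(colat, psi, params.vault_semiaxes)
    layers = [outer - normal * (params.shell_thickness * k / nt) for k in range(nt + 1)]
    vault_nodes = np.concatenate([l.reshape(-1, 3) for l in layers])
    vault_nodes = _apply_interfrontal_taper(vault_nodes, params, np.tile(psi.ravel(), nt + 1),
                                            np.tile(colat.ravel(), nt + 1))

    def vid(i, j, k):
        return k * N * N + i * N + j

    hexes = []
    hex_meta = []  # ('vault', i, j, k)
    for k in range(nt):
        for i in range(n_cells):
            for j in range(n_cells):
                hexes.append(
                    [
                        vid(i, j, k), vid(i + 1, j, k), vid(i + 1, j + 1, k), vid(i, j + 1, k),
                        vid(i, j, k + 1), vid(i + 1, j, k + 1), vid(i + 1, j + 1, k + 1),
                        vid(i, j + 1, k + 1),
                    ]
                )
                hex_meta.append(("vault", i, j, k))

    # --- face block: a "J-profile" sweep from the anterior rim -------------
    # The central anterior rim strip (|azimuth| <~ 28 deg) is swept downward
    # as a facial wall, through a quarter-circle bend, and posteriorly as a
    # flat horizontal hard-palate plate of constant shell thickness.  The
    # sweep keeps cell aspect ratios bounded (no sliver elements) and shares
    # the rim nodes, so the face is conformingly tied to the vault.
    pw, pd = params.palate_dimensions
    mid = (N - 1) // 2
    nasion_xyz = vault_nodes[vid(N - 1, mid, 0)].copy()
    x0, y0 = nasion_xyz[0], nasion_xyz[1]

    b_strip = 0.62  # rim strip |b| <= 0.62  ->  |azimuth| <= ~28 deg
    j_lo = int(np.ceil((1.0 - b_strip) / 2.0 * (N - 1)))
    j_hi = N - 1 - j_lo
    Nf = j_hi - j_lo + 1  # face columns (nodes)
    r_bend = min(10.0, 0.4 * pd, 0.4 * params.face_depth)
    L_wall = params.face_depth - r_bend
    L_arc = r_bend * np.pi / 2.0
    L_pal = pd - r_bend
    L_tot = L_wall + L_arc + L_pal
    nl = max(4, int(round(L_tot / edge)))

    def _curve(s):
        """Mid-sagittal sweep curve: (x, y) and tangent angle theta
        (0 = descending, pi/2 = horizontal-posterior)."""
        if s <= L_wall:
            return x0 - s, y0, 0.0
        if s <= L_wall + L_arc:
            beta = (s - L_wall) / r_bend
            return (
                x0 - L_wall - r_bend * np.sin(beta),
                y0 - r_bend + r_bend * np.cos(beta),
                beta,
            )
        t = s - L_wall - L_arc
        return x0 - L_wall - r_bend, y0 - r_bend - t, np.pi / 2.0

    s_levels = np.linspace(0.0, L_tot, nl + 1)
    l_bend = int(np.searchsorted(s_levels, L_wall + L_arc - 1e-9))  # first palate level

    rim_z = np.array([vault_nodes[vid(N - 1, j, 0)][2] for j in range(j_lo, j_hi + 1)])
    z_pal = (pw / 2.0) * rim_z / np.abs(rim_z).max()

    n_vault_nodes = len(vault_nodes)
    face_nodes = []

    def fid(jf, k, l):
        # jf is the face-local column (0..Nf-1); l = 0 is the shared rim level
        if l == 0:
            return vid(N - 1, j_lo + jf, k)
        return n_vault_nodes + (l - 1) * Nf * (nt + 1) + k * Nf + jf

    th = params.shell_thickness
    for l in range(1, nl + 1):
        s = s_levels[l]
        mx, my, theta = _curve(s)
        w = 1.0 if L_wall == 0 else float(np.clip(s / L_wall, 0.0, 1.0))
        wz = float(np.clip(s / (L_wall + L_arc), 0.0, 1.0))
        ek = np.array([np.sin(theta), -np.cos(theta)])  # thickness direction
        for k in range(nt + 1):
            for jf in range(Nf):
                T = vault_nodes[vid(N - 1, j_lo + jf, k)]
                z = (1 - wz) * T[2] + wz * z_pal[jf]
                ideal = np.array(
                    [mx + ek[0] * (k / nt) * th, my + ek[1] * (k / nt) * th, z]
                )
                translated = np.array([T[0] + (mx - x0), T[1] + (my - y0), z])
                face_nodes.append((1 - w) * translated + w * ideal)
    nodes0 = np.vstack([vault_nodes, np.asarray(face_nodes)])

    for l in range(nl):
        for k in range(nt):
            for jf in range(Nf - 1):
                hexes.append(
                    [
                        fid(jf, k, l + 1), fid(jf + 1, k, l + 1), fid(jf + 1, k + 1, l + 1),
                        fid(jf, k + 1, l + 1),
                        fid(jf, k, l), fid(jf + 1, k, l), fid(jf + 1, k + 1, l),
                        fid(jf, k + 1, l),
                    ]
                )
                hex_meta.append(("face", jf, k, l))
    hexes = np.asarray(hexes, dtype=np.int64)
    face_info = {"Nf": Nf, "nl": nl, "l_bend": l_bend, "s_levels": s_levels,
                 "L_wall": L_wall, "L_arc": L_arc}

    # --- subdivide to conforming tets --------------------------------------
    nodes, tets, tet_hex, tet_face = hexes_to_tets(nodes0, hexes)

    # --- element region labels ---------------------------------------------
    hex_region = _label_hexes(nodes0, hexes, hex_meta, params, face_info)
    element_region = hex_region[tet_hex]

    # --- boundary facets -----------------------------------------------------
    facets, facet_labels = _label_facets(
        nodes, tets, tet_hex, tet_face, hex_meta, hexes, params, nt, face_info, hex_region
    )

    # --- node sets -----------------------------------------------------------
    node_sets = _build_node_sets(
        nodes0, params, N, nt, vid, fid, psi, colat, face_info
    )

    mesh = LabeledMesh(
        nodes=nodes,
        tets=tets,
        element_region=element_region,
        facets=facets,
        facet_labels=facet_labels,
        node_sets=node_sets,
        metadata={
            "params": params,
            "n_grid": N,
            "metopic_arc_param": _metopic_arc_param(nodes0, hexes, hex_region, tet_hex, params),
        },
    )

    # translate so the TMJ midpoint is the coordinate origin
    tmj_mid = 0.5 * (
        mesh.nodes[mesh.node_sets["tmj_L"]].mean(axis=0)
        + mesh.nodes[mesh.node_sets["tmj_R"]].mean(axis=0)
    )
    tmj_mid[2] = 0.0  # exact by symmetry; keep midline nodes at z = 0 exactly
    mesh.nodes -= tmj_mid

    if params.landmark_overrides:
        for name, coord in params.landmark_overrides.items():
            d = np.linalg.norm(mesh.nodes - np.asarray(coord, dtype=float), axis=1)
            mesh.node_sets[name] = np.array([int(np.argmin(d))])

    if params.metopic_closure_fraction > 0:
        mesh = apply_metopic_closure(mesh, params.metopic_closure_fraction)

    missing = [s for s in REQUIRED_NODE_SETS if len(mesh.node_sets.get(s, ())) == 0]
    if missing:
        raise GeometryError(f"generator produced empty node sets: {missing}")
    return mesh


def _apply_interfrontal_taper(nodes, params, psi_flat, colat_flat):
    """Narrow the frontal sectors toward a mid-sagittal ridge (trigonocephaly)."""
    if params.interfrontal_angle == PHYSIOLOGIC_INTERFRONTAL_ANGLE:
        return nodes
    tau = np.tan(np.radians(params.interfrontal_angle) / 2) / np.tan(
        np.radians(PHYSIOLOGIC_INTERFRONTAL_ANGLE) / 2
    )
    psi_deg = np.degrees(np.abs(psi_flat))
    colat_deg = np.degrees(colat_flat)
    w_psi = np.clip(np.cos(np.radians(psi_deg / 70.0 * 90.0)), 0.0, None) ** 2
    w_psi[psi_deg >= 70.0] = 0.0
    af_deg = np.degrees(_FONTANELLE_ANT_RADIUS / np.mean(params.vault_semiaxes))
    w_colat = np.clip((colat_deg - af_deg) / (40.0 - af_deg), 0.0, 1.0)
    shrink = 1.0 - (1.0 - tau) * w_psi * w_colat
    out = nodes.copy()
    out[:, 2] *= shrink
    return out


def _suture_paths(params):
    """Suture centre-lines as (colat_deg, psi_deg) polylines (left side and
    midline; right side is mirrored)."""
    af = np.degrees(_FONTANELLE_ANT_RADIUS / np.mean(params.vault_semiaxes))
    pf = np.degrees(_FONTANELLE_POST_RADIUS / np.mean(params.vault_semiaxes))
    paths = {
        "metopic": [(af, 0.0), (_RIM_ANTERIOR - 6.0, 0.0)],
        "sagittal": [(af, 180.0), (_PF_COLAT - pf, 180.0)],
        # the coronal strip continues below the pterion as the (cartilaginous
        # in infancy) sphenofrontal/sphenosquamosal complex toward the base
        "coronal_L": [(af, _CORONAL_PSI), (104.0, _CORONAL_PSI)],
        # lambdoid runs from lambda down to the asterion/occipitomastoid rim,
        # so the occipital plate is bounded by compliant joints on all sides
        "lambdoid_L": [(_PF_COLAT + pf, 180.0), (122.0, 133.0)],
        # squamous arcs over the ear, posterior to the coronal complex
        "squamous_L": [(_SQUAMOUS_COLAT, _CORONAL_PSI + 4.0), (_SQUAMOUS_COLAT, 128.0)],
    }
    return paths


def _sample_path(path, params, n=160):
    """Densely sample a (colat_deg, psi_deg) polyline on the outer dome, 3D."""
    pts = []
    path = np.asarray(path, dtype=float)
    for seg in range(len(path) - 1):
        t = np.linspace(0, 1, n)
        colat = np.radians(path[seg, 0] + t * (path[seg + 1, 0] - path[seg, 0]))
        psi = np.radians(path[seg, 1] + t * (path[seg + 1, 1] - path[seg, 1]))
        pts.append(_dome_point(colat, psi, params.vault_semiaxes))
    return np.concatenate(pts)


def _label_hexes(nodes0, hexes, hex_meta, params, face_info):
    """Region label per hex (inherited by its 24 tets)."""
    from scipy.spatial import cKDTree

    n_hex = len(hexes)
    region = np.array(["bone"] * n_hex, dtype=object)
    cents = nodes0[hexes].mean(axis=1)
    half_w = params.suture_width / 2.0
    r_mean = float(np.mean(params.vault_semiaxes))
    af_deg = np.degrees(_FONTANELLE_ANT_RADIUS / r_mean)

    is_vault = np.array([m[0] == "vault" for m in hex_meta])
    vault_ids = np.flatnonzero(is_vault)
    # recompute the (colat, psi) parameters of vault hex centroids from the
    # untapered dome: use the direction of the centroid about the dome centre
    c = cents[vault_ids]
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    colat = np.degrees(np.arctan2(np.hypot(y / params.vault_semiaxes[1] * r_mean,
                                           z / params.vault_semiaxes[2] * r_mean),
                                  x / params.vault_semiaxes[0] * r_mean))
    psi = np.degrees(np.arctan2(z, y))
    rim = _rim_colatitude(np.radians(psi))

    # face block labels: levels past the bend form the hard-palate plate
    l_bend = face_info["l_bend"]
    for h, meta in enumerate(hex_meta):
        if meta[0] == "face":
            region[h] = "palate_bone" if meta[3] >= l_bend else "face_bone"

    # fontanelles
    ant_f = colat < af_deg
    pf_point = _dome_point(np.radians(_PF_COLAT), np.pi, params.vault_semiaxes)
    pf_dist = np.linalg.norm(c - pf_point, axis=1)
    post_f = pf_dist < _FONTANELLE_POST_RADIUS + half_w / 2

    # nasofrontal band at the anterior rim, synchondrosis band at the posterior rim
    naso_band = np.degrees(params.suture_width / r_mean)
    naso = (np.abs(psi) < 26.0) & (colat > rim - naso_band) & ~ant_f
    synch_band = np.degrees(1.5 * params.suture_width / r_mean)
    synch = (np.abs(psi) > 150.0) & (colat > rim - synch_band)

    labels = np.array(["bone"] * len(vault_ids), dtype=object)
    labels[naso] = "nasofrontal"
    labels[synch] = "synchondrosis"

    # arc sutures: distance to sampled centre-lines, applied per grid column
    # (full shell thickness) with a nearest-column chain so every strip stays
    # connected at any resolvable edge length
    col_key = np.array([(m[1], m[2]) for m in (hex_meta[i] for i in vault_ids)])
    col_ids = {}
    for idx, key in enumerate(map(tuple, col_key)):
        col_ids.setdefault(key, []).append(idx)
    col_list = list(col_ids)
    col_index = {k: i for i, k in enumerate(col_list)}
    n_cells_j = max(k[1] for k in col_list) + 1
    # mirror image of column (i, j) about z = 0 is (i, n_cells_j - 1 - j)
    col_mirror = np.array(
        [col_index[(k[0], n_cells_j - 1 - k[1])] for k in col_list]
    )
    col_cent = np.array([c[col_ids[k]].mean(axis=0) for k in col_list])
    col_colat = np.array([colat[col_ids[k]].mean() for k in col_list])
    col_psi = np.array([psi[col_ids[k]].mean() for k in col_list])
    col_rim = _rim_colatitude(np.radians(col_psi))
    col_pf = np.array([post_f[col_ids[k]].any() for k in col_list])

    paths = _suture_paths(params)
    for name, path in paths.items():
        sides = [(name, 1.0)]
        if name.endswith("_L"):
            sides.append((name.replace("_L", "_R"), -1.0))
        for side_name, sgn in sides:
            pts = _sample_path([(cl, sgn * ps) for cl, ps in path], params, n=200)
            d, _ = cKDTree(pts).query(col_cent)
            hit = d < half_w
            hit[cKDTree(col_cent).query(pts)[1]] = True  # nearest-column chain
            if name in ("metopic", "sagittal"):
                # midline strips must be exactly mirror symmetric; the chain
                # can break equidistant ties one-sidedly, so symmetrize
                hit |= hit[col_mirror]
            if name == "metopic":
                hit &= (col_colat >= af_deg) & (col_colat < col_rim - naso_band)
            if name == "sagittal":
                hit &= (col_colat >= af_deg) & ~col_pf
            if name.startswith("coronal") or name.startswith("lambdoid"):
                hit &= col_colat >= af_deg
            for ci in np.flatnonzero(hit):
                for idx in col_ids[col_list[ci]]:
                    if labels[idx] == "bone":
                        labels[idx] = side_name

    labels[ant_f] = "anterior_fontanelle"
    labels[post_f] = "posterior_fontanelle"
    region[vault_ids] = labels
    return region


def _metopic_arc_param(nodes0, hexes, hex_region, tet_hex, params):
    """Arc-length parameter of each metopic tet: 0 at the nasion end,
    1 at the anterior-fontanelle end."""
    r_mean = float(np.mean(params.vault_semiaxes))
    af_deg = np.degrees(_FONTANELLE_ANT_RADIUS / r_mean)
    naso_band = np.degrees(params.suture_width / r_mean)
    top, bottom = af_deg, _RIM_ANTERIOR - naso_band
    cents = nodes0[hexes].mean(axis=1)
    colat = np.degrees(
        np.arctan2(np.hypot(cents[:, 1] / params.vault_semiaxes[1] * r_mean,
                            cents[:, 2] / params.vault_semiaxes[2] * r_mean),
                   cents[:, 0] / params.vault_semiaxes[0] * r_mean)
    )
    s_hex = np.clip((bottom - colat) / (bottom - top), 0.0, 1.0)
    s = np.where(hex_region[tet_hex] == "metopic", s_hex[tet_hex], np.nan)
    return s


def apply_metopic_closure(mesh: LabeledMesh, fraction: float) -> LabeledMesh:
    """Relabel a window of the metopic suture to bone.

    Closure follows the clinical anterior-to-posterior "zipper": it seeds just
    above the nasion (10 % of arc length) and grows in both directions in
    proportion, so the nasion-adjacent tip and the fontanelle-adjacent end
    close last, the window length equals ``fraction`` x suture length, and
    windows nest as the fraction grows.  Only labels change — node
    coordinates and connectivity are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise GeometryError("closure fraction must lie in [0, 1]")
    s = mesh.metadata.get("metopic_arc_param")
    if s is None:
        raise GeometryError("mesh has no metopic arc parameterization")
    out = LabeledMesh(
        nodes=mesh.nodes,
        tets=mesh.tets,
        element_region=mesh.element_region.copy(),
        facets=mesh.facets,
        facet_labels=mesh.facet_labels,
        node_sets=dict(mesh.node_sets),
        metadata=dict(mesh.metadata),
    )
    if fraction == 0.0:
        return out
    seed = 0.1
    lo = seed * (1.0 - fraction)
    hi = seed + fraction * (1.0 - seed)
    close = (out.element_region == "metopic") & (s >= lo - 1e-12) & (s <= hi + 1e-12)
    out.element_region[close] = "bone"
    out.metadata["metopic_closure_fraction"] = fraction
    return out


def _label_facets(
    nodes, tets, tet_hex, tet_face, hex_meta, hexes, params, nt, face_info, hex_region
):
    """Classify unshared hex faces into surface facet labels.

    Every tet's face-0 triangle (nodes 0, 1, 2 = quad edge + face centroid)
    lies on its parent hex face; it is a boundary triangle iff that hex face
    is unshared.
    """
    unshared = set(boundary_hex_faces(hexes))
    tris, labels = [], []
    r_mean = float(np.mean(params.vault_semiaxes))

    # temporal-fossa windows (colat range, azimuth range, degrees); the fossa
    # lies mostly posterior to the coronal complex and its upper margin (the
    # superior temporal line) stays well below the vertex
    att_windows = {
        "anterior_temporalis": ((58.0, 88.0), (76.0, 100.0)),
        "posterior_temporalis": ((58.0, 90.0), (102.0, 132.0)),
    }
    # the masseters originate along the zygomatic-arch span; with no arch
    # meshed, their origins are the lower lateral rim band under it
    masseter_bands = {
        "superficial_masseter": (48.0, 66.0),
        "deep_masseter": (66.0, 88.0),
    }

    n_tets = len(tets)
    for t in range(n_tets):
        h, f = tet_hex[t], tet_face[t]
        if (h, f) not in unshared:
            continue
        tri = tets[t, :3]
        kind = hex_meta[h][0]
        label = None
        cent = nodes[tri].mean(axis=0)
        if kind == "vault":
            k = hex_meta[h][3]
            if f == 0 and k == 0:
                label = "ectocranial"
                colat = np.degrees(
                    np.arctan2(
                        np.hypot(cent[1] / params.vault_semiaxes[1] * r_mean,
                                 cent[2] / params.vault_semiaxes[2] * r_mean),
                        cent[0] / params.vault_semiaxes[0] * r_mean,
                    )
                )
                psi = np.degrees(np.arctan2(cent[2], cent[1]))
                rim = float(_rim_colatitude(np.radians(psi)))
                side = "L" if psi > 0 else "R"
                apsi = abs(psi)
                # muscles originate on bone, never on suture surfaces
                if hex_region[h] == "bone":
                    for m, ((c0, c1), (p0, p1)) in att_windows.items():
                        if c0 <= colat <= c1 and p0 <= apsi <= p1:
                            label = f"attachment:{m}:{side}"
                    for m, (p0, p1) in masseter_bands.items():
                        if p0 <= apsi <= p1 and rim - 14.0 < colat < rim - 2.0:
                            label = f"attachment:{m}:{side}"
            elif f == 1 and k == nt - 1:
                label = "endocranial"
        else:  # face block
            jf, k, l = hex_meta[h][1:]
            Nf, nl, l_bend = face_info["Nf"], face_info["nl"], face_info["l_bend"]
            s_mid = 0.5 * (face_info["s_levels"][l] + face_info["s_levels"][l + 1])
            in_bend = face_info["L_wall"] <= s_mid <= face_info["L_wall"] + face_info["L_arc"]
            if f == 2 and k == 0:  # outer / inferior surface of the sweep
                if l >= l_bend:
                    # horizontal plate underside: margin = alveolar ridge
                    label = "alveolar" if jf in (0, Nf - 2) else "palate"
                elif in_bend:
                    label = "alveolar"  # curving anterior underside
            elif f == 0 and l == nl - 1 and abs(cent[2]) > 4.0:
                # posterior palate edge, paired patches ~ pterygoid plates
                side = "L" if cent[2] > 0 else "R"
                label = f"attachment:medial_pterygoid:{side}"
        if label is not None:
            # the tet's first three nodes wind toward its interior body
            # centroid; flip for an outward surface normal
            tris.append(tri[[0, 2, 1]])
            labels.append(label)
    tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
    labels = np.asarray(labels, dtype=object)
    return tris, labels


def _build_node_sets(nodes0, params, N, nt, vid, fid, psi, colat, face_info):
    mid = (N - 1) // 2
    sets = {}

    # vault rim nodes with azimuth near the TMJ meridian, on the lateral rim
    psi_deg = np.degrees(psi)
    lat_rim_L, lat_rim_R = [], []
    for i in range(N):
        for j in (0, N - 1):
            p = psi_deg[i, j]
            for k in range(nt + 1):
                if abs(abs(p) - _TMJ_PSI) < 7.0:
                    (lat_rim_L if p > 0 else lat_rim_R).append(vid(i, j, k))
    sets["tmj_L"] = np.array(sorted(lat_rim_L), dtype=np.int64)
    sets["tmj_R"] = np.array(sorted(lat_rim_R), dtype=np.int64)

    # posterior rim: foramen magnum ring
    fm = []
    for j in range(N):
        p = psi_deg[0, j]
        if abs(abs(p) - 180.0) < 26.0 or np.isnan(p):
            for k in range(nt + 1):
                fm.append(vid(0, j, k))
    sets["foramen_magnum"] = np.array(sorted(fm), dtype=np.int64)

    # midline landmarks
    sets["nasion"] = np.array([vid(N - 1, mid, 0)], dtype=np.int64)
    sets["bregma"] = np.array([vid(mid, mid, 0)], dtype=np.int64)
    colat_deg = np.degrees(colat)
    target = _RIM_ANTERIOR - 10.0
    best_i = min(range(N), key=lambda i: abs(colat_deg[i, mid] - target) + (0 if i > mid else 1e6))
    sets["glabella"] = np.array([vid(best_i, mid, 0)], dtype=np.int64)

    # alveolar / bite landmarks on the palate margin (face-local columns)
    Nf, nl, l_bend = face_info["Nf"], face_info["nl"], face_info["l_bend"]
    fmid = (Nf - 1) // 2
    sets["latch_midline"] = np.array(
        sorted({fid(fmid - 1, 0, l_bend), fid(fmid, 0, l_bend), fid(fmid + 1, 0, l_bend)}),
        dtype=np.int64,
    )
    zb = np.array([nodes0[fid(jf, 0, nl)][2] for jf in range(Nf)])
    pw = params.palate_dimensions[0]
    j_inc = int(np.argmin(np.abs(zb - (-0.30 * pw / 2))))
    sets["bite_R_lateral_incisor"] = np.array(
        sorted({fid(j_inc, 0, l_bend), fid(j_inc + 1, 0, l_bend)}), dtype=np.int64
    )
    l_m1 = l_bend + max(1, (nl - l_bend) // 2)
    sets["bite_R_molar1"] = np.array(
        sorted({fid(0, 0, l_m1), fid(1, 0, l_m1)}), dtype=np.int64
    )
    sets["bite_R_molar2"] = np.array(
        sorted({fid(0, 0, nl), fid(1, 0, nl)}), dtype=np.int64
    )

    # analysis regions (vault outer-surface nodes)
    frontal, supra, lat_orb = [], [], []
    for i in range(N):
        for j in range(N):
            p, cl = psi_deg[i, j], colat_deg[i, j]
            rim = float(_rim_colatitude(np.radians(p)))
            ap = abs(p)
            if 12.0 <= ap <= 48.0 and 28.0 <= cl <= 56.0:
                frontal.append(vid(i, j, 0))
            if ap < 45.0 and rim - 14.0 < cl < rim - 4.0:
                supra.append(vid(i, j, 0))
            if 40.0 <= ap <= 58.0 and rim - 16.0 < cl < rim - 2.0:
                lat_orb.append(vid(i, j, 0))
    sets["frontal_eminence"] = np.array(sorted(frontal), dtype=np.int64)
    sets["supraorbital"] = np.array(sorted(supra), dtype=np.int64)
    sets["lateral_orbital"] = np.array(sorted(lat_orb), dtype=np.int64)
    midface = [
        fid(jf, k, l) for l in range(1, nl + 1) for k in range(nt + 1) for jf in range(Nf)
    ]
    sets["midface"] = np.array(sorted(midface), dtype=np.int64)
    return sets


def default_attachments(mesh: LabeledMesh) -> list[MuscleAttachment]:
    """The ten default muscle attachments (5 muscles x 2 sides).

    Origin patches are the labeled ``attachment:<muscle>:<side>`` facet sets
    on the mesh; insertion centroids are fixed mandibular points in the
    TMJ-origin frame (the mandible itself is not meshed).
    """
    out = []
    for muscle in MUSCLES:
        for side in ("L", "R"):
            label = f"attachment:{muscle}:{side}"
            if len(mesh.facets_of_label(label)) == 0:
                raise GeometryError(f"mesh is missing attachment facets {label!r}")
            ins = np.asarray(_INSERTIONS_L[muscle], dtype=float).copy()
            if side == "R":
                ins[2] = -ins[2]
            out.append(
                MuscleAttachment(
                    muscle=muscle, side=side, origin_facets=label, insertion_centroid=ins
                )
            )
    return out


def origin_centroid(mesh: LabeledMesh, facet_label: str) -> np.ndarray:
    """Area-weighted centroid of a facet patch."""
    fids = mesh.facets_of_label(facet_label)
    if fids.size == 0:
        raise GeometryError(f"empty facet patch {facet_label!r}")
    tris = mesh.facets[fids]
    p = mesh.nodes[tris]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    cents = p.mean(axis=1)
    return (cents * areas[:, None]).sum(axis=0) / areas.sum()
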