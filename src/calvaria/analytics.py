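"""Suture-level strain statistics and mid-sagittal polar profiles.

Cross-suture (axial) strain is the normal strain component perpendicular to
each suture's main direction: medial-lateral eps_zz for the nasofrontal,
metopic and sagittal sutures; anterior-posterior eps_yy for the coronals;
superior-inferior eps_xx for the squamous sutures; for the lambdoids the
larger-magnitude of the suture-averaged eps_zz and eps_xx.  Positive values
are tension, negative compression.

All suture statistics average *nodal* strain over the suture's endo- and
ectocranial surface nodes (pooled by default), then derive quantities from
the averages.  Cumulative shear is |mean eps_xy| + |mean eps_xz| +
|mean eps_yz| — magnitudes of the averages, not averages of magnitudes.

The mid-sagittal profile maps midline surface nodes to the polar angle
theta = atan2(x, y) (degrees; 0 at the nasion direction, 90 at the vertex,
-> 180 posteriorly) and bins strain along the nasion -> metopic ->
anterior fontanelle -> sagittal -> posterior fontanelle path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import COMPONENTS, StrainField
from .mesh import LabeledMesh, SUTURE_REGIONS

#: sutures reported in the per-suture tables (basicranial strip excluded)
REPORTED_SUTURES = tuple(s for s in SUTURE_REGIONS if s != "synchondrosis")

MIDLINE_SUTURES = (
    "nasofrontal",
    "metopic",
    "anterior_fontanelle",
    "sagittal",
    "posterior_fontanelle",
)

_CROSS_COMPONENT = {
    "nasofrontal": "zz",
    "metopic": "zz",
    "sagittal": "zz",
    "anterior_fontanelle": "zz",
    "posterior_fontanelle": "zz",
    "coronal_L": "yy",
    "coronal_R": "yy",
    "squamous_L": "xx",
    "squamous_R": "xx",
    "synchondrosis": "zz",
}


class AnalyticsError(ValueError):
    pass


@dataclass
class SutureSummary:
    suture: str
    n_nodes: int
    mean: dict  # component -> microstrain
    cross_axial: float  # microstrain
    cross_component: str
    cumulative_shear: float  # microstrain
    median: float  # of nodal cross-axial values, microstrain
    iqr: float


@dataclass
class MidlineProfile:
    theta: np.ndarray  # bin centers, degrees, strictly increasing
    value: np.ndarray  # per-bin statistic, microstrain
    label: np.ndarray  # dominant suture per bin
    count: np.ndarray  # nodes per bin
    component: str


def suture_surface_nodes(mesh: LabeledMesh, suture: str, surfaces=("ectocranial", "endocranial")):
    """Nodes of a suture lying on the (pooled) endo/ectocranial surfaces."""
    if suture not in SUTURE_REGIONS:
        raise AnalyticsError(f"unknown suture label {suture!r}")
    surf = mesh.surface_node_ids(surfaces)
    region_nodes = mesh.region_node_ids(suture)
    nodes = np.intersect1d(surf, region_nodes)
    return nodes


def suture_node_partition(mesh: LabeledMesh, sutures=SUTURE_REGIONS) -> dict:
    """Assign every suture surface node to exactly one suture.

    Junction nodes (shared by elements of two sutures, e.g. where the
    metopic meets the anterior fontanelle) go to the suture listed first in
    ``sutures``; the result is a deterministic partition used by the midline
    profile so no node is double-counted.
    """
    assigned = {}
    for s in sutures:
        if len(mesh.elements_of_region(s)) == 0:
            continue
        for n in suture_surface_nodes(mesh, s):
            assigned.setdefault(int(n), s)
    return assigned


def _shear_scale(engineering_shear: bool) -> float:
    return 2.0 if engineering_shear else 1.0


def cross_suture_strain(
    strain: StrainField,
    mesh: LabeledMesh,
    suture: str,
    engineering_shear: bool = False,
    surfaces=("ectocranial", "endocranial"),
) -> SutureSummary:
    """The per-suture summary row: component means, cross-axial strain by the
    per-suture convention, and cumulative shear, all in microstrain."""
    nodes = suture_surface_nodes(mesh, suture, surfaces)
    if nodes.size == 0:
        raise AnalyticsError(f"suture {suture!r} has no surface nodes")
    eps = strain.node_strain[nodes] * 1e6  # microstrain
    sh = _shear_scale(engineering_shear)
    means = {c: float(eps[:, i].mean()) * (sh if i >= 3 else 1.0)
             for i, c in enumerate(COMPONENTS)}

    if suture.startswith("lambdoid"):
        comp = "zz" if abs(means["zz"]) >= abs(means["xx"]) else "xx"
    else:
        comp = _CROSS_COMPONENT[suture]
    idx = COMPONENTS.index(comp)
    nodal_cross = eps[:, idx]
    q25, q50, q75 = np.percentile(nodal_cross, [25, 50, 75])
    return SutureSummary(
        suture=suture,
        n_nodes=int(nodes.size),
        mean=means,
        cross_axial=means[comp],
        cross_component=comp,
        cumulative_shear=abs(means["xy"]) + abs(means["xz"]) + abs(means["yz"]),
        median=float(q50),
        iqr=float(q75 - q25),
    )


def cumulative_shear(
    strain: StrainField, mesh: LabeledMesh, suture: str, engineering_shear: bool = False
) -> float:
    """|mean eps_xy| + |mean eps_xz| + |mean eps_yz| over suture surface
    nodes, microstrain (averages first, magnitudes second)."""
    nodes = suture_surface_nodes(mesh, suture)
    if nodes.size == 0:
        raise AnalyticsError(f"suture {suture!r} has no surface nodes")
    eps = strain.node_strain[nodes] * 1e6
    sh = _shear_scale(engineering_shear)
    return float(sum(abs(eps[:, i].mean()) * sh for i in (3, 4, 5)))


def theta(coords) -> np.ndarray:
    """Polar angle (degrees) of node coordinates in the mid-sagittal plane.

    Quadrant-safe: 0 deg at pure +y (anterior, nasion direction), 90 deg at
    pure +x (vertex), approaching 180 deg toward -y (posterior), continuous
    along the superior midline arc.
    """
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    x, y = c[:, 0], c[:, 1]
    if np.any((x == 0) & (y == 0)):
        raise AnalyticsError("theta undefined at the origin")
    out = np.degrees(np.arctan2(x, y))
    return out if out.size > 1 else float(out[0])


def midsagittal_profile(
    strain: StrainField,
    mesh: LabeledMesh,
    component: str = "zz",
    bin_width: float = 2.0,
    engineering_shear: bool = False,
    signed: bool = True,
) -> MidlineProfile:
    """Theta-binned strain along the midline suture path.

    component: a tensor component name ("zz", ...) for per-bin means, or
    "cumulative_shear" for the within-bin cumulative-shear statistic.
    Bins are anchored at theta = 0; empty bins are omitted.
    """
    if bin_width <= 0:
        raise AnalyticsError("bin_width must be positive")
    node_lists, labels = [], []
    for suture in MIDLINE_SUTURES:
        ids = suture_surface_nodes(mesh, suture)
        node_lists.append(ids)
        labels += [suture] * len(ids)
    nodes = np.concatenate(node_lists)
    labels = np.asarray(labels, dtype=object)
    # a node shared between adjacent midline sutures contributes once
    nodes, first = np.unique(nodes, return_index=True)
    labels = labels[first]

    th = theta(mesh.nodes[nodes])
    bins = np.floor(th / bin_width).astype(int)
    sh = _shear_scale(engineering_shear)

    eps = strain.node_strain[nodes] * 1e6
    rows = []
    for b in sorted(set(bins)):
        sel = bins == b
        center = (b + 0.5) * bin_width
        sub = eps[sel]
        if component == "cumulative_shear":
            val = sum(abs(sub[:, i].mean()) * sh for i in (3, 4, 5))
        else:
            i = COMPONENTS.index(component)
            scale = sh if i >= 3 else 1.0
            val = sub[:, i].mean() * scale
            if not signed:
                val = abs(val)
        lab, counts = np.unique(labels[sel].astype(str), return_counts=True)
        rows.append((center, float(val), lab[np.argmax(counts)], int(sel.sum())))
    rows.sort()
    return MidlineProfile(
        theta=np.array([r[0] for r in rows]),
        value=np.array([r[1] for r in rows]),
        label=np.array([r[2] for r in rows], dtype=object),
        count=np.array([r[3] for r in rows]),
        component=component,
    )


def regional_summary(field, mesh: LabeledMesh, region: str, thresholds=(20.0, 50.0, 70.0)):
    """Descriptive stats of a per-node scalar field over an analysis region.

    field is in the caller's units (typically microstrain or MPa); returns
    dict with mean, max and the percentage of nodes above each threshold.
    """
    if region not in mesh.node_sets:
        raise AnalyticsError(f"unknown analysis region {region!r}")
    ids = mesh.node_sets[region]
    if len(ids) == 0:
        raise AnalyticsError(f"analysis region {region!r} is empty")
    vals = np.asarray(field, dtype=float)[ids]
    out = {"region": region, "n_nodes": int(len(ids)), "mean": float(vals.mean()),
           "max": float(vals.max())}
    for t in thresholds:
        out[f"pct_above_{t:g}"] = float(100.0 * np.mean(vals > t))
    return out


def suture_table(
    strain: StrainField, mesh: LabeledMesh, engineering_shear: bool = False
) -> pd.DataFrame:
    """Per-suture component table (one row per reported suture)."""
    rows = []
    for suture in REPORTED_SUTURES:
        if len(mesh.elements_of_region(suture)) == 0:
            continue  # e.g. fully closed metopic
        s = cross_suture_strain(strain, mesh, suture, engineering_shear)
        row = {"suture": suture, **{f"eps_{c}": s.mean[c] for c in COMPONENTS}}
        row.update(
            cross_axial=s.cross_axial,
            cross_component=s.cross_component,
            cumulative_shear=s.cumulative_shear,
            median=s.median,
            iqr=s.iqr,
            n_nodes=s.n_nodes,
        )
        rows.append(row)
    return pd.DataFrame(rows)
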