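"""Virtual quadripolar lead placement and combinatorics.

Five idealized epicardial vein tracks run down the LV free wall, anchored to
the basal AHA segments: inferior (IN, border 4/5), inferolateral (IL, centre
5), lateral (LA, border 5/6), anterolateral (AL, centre 6) and anterior (AN,
border 6/1).  Along each vein, 8 candidate electrode positions (named "a",
most basal, through "h", most apical) span 52.5 mm at 7.5 mm pitch, with "a"
at 80% of the apicobasal distance.  A pacing configuration activates 1 or 2
LV electrodes together with the RV electrode; a lead design is a choice of
4 of the 8 positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .anatomy import EPI, LV_WALL, RV_ENDO, VentricularMesh
from .coordinates import Aha17Map, SEGMENT_CENTRE_DEG, VentricularCoordinates

__all__ = [
    "Vein",
    "VeinLine",
    "Lead",
    "PacingConfiguration",
    "LeadDesign",
    "VEINS",
    "VEIN_ORDER",
    "ELECTRODE_LETTERS",
    "locate_vein_line",
    "place_electrodes",
    "place_rv_electrode",
    "enumerate_configurations",
    "enumerate_lead_designs",
]

ELECTRODE_LETTERS = "abcdefgh"
VEIN_ORDER = ("IN", "IL", "LA", "AL", "AN")


@dataclass(frozen=True)
class Vein:
    """A vein track at a fixed rotational angle derived from AHA anchors."""

    name: str
    aha_anchor: str
    angle_deg: float


def _border(seg_a: int, seg_b: int) -> float:
    ca, cb = SEGMENT_CENTRE_DEG[seg_a], SEGMENT_CENTRE_DEG[seg_b]
    d = (cb - ca + 180.0) % 360.0 - 180.0
    return ca + d / 2.0


VEINS = {
    "IN": Vein("IN", "border AHA 4/5", _border(4, 5)),
    "IL": Vein("IL", "centre AHA 5", SEGMENT_CENTRE_DEG[5]),
    "LA": Vein("LA", "border AHA 5/6", _border(5, 6)),
    "AL": Vein("AL", "centre AHA 6", SEGMENT_CENTRE_DEG[6]),
    "AN": Vein("AN", "border AHA 6/1", _border(6, 1)),
}


@dataclass
class VeinLine:
    """Epicardial polyline of a vein, ordered basal (z = 0.8) to apical."""

    vein: Vein
    points: np.ndarray  # (n, 3) mm
    z: np.ndarray  # apicobasal coordinate per point
    arc: np.ndarray  # cumulative arc length from the basal end, mm

    @property
    def length(self) -> float:
        return float(self.arc[-1])


@dataclass
class Lead:
    """Eight electrode positions along one vein."""

    vein: Vein
    electrode_nodes: np.ndarray  # (8,) node ids, basal -> apical
    electrode_labels: tuple  # ("a", ..., "h")
    arc_positions: np.ndarray  # (8,) mm along the vein line (snapped nodes)
    ideal_arc: np.ndarray  # (8,) mm, exact 7.5 mm pitch positions

    def node_of(self, letter: str) -> int:
        return int(self.electrode_nodes[ELECTRODE_LETTERS.index(letter)])


@dataclass(frozen=True)
class PacingConfiguration:
    """1 or 2 active LV electrodes plus the always-on RV electrode."""

    name: str  # sorted letters, e.g. "ad"
    active_lv_electrodes: tuple
    rv_electrode: int


@dataclass(frozen=True)
class LeadDesign:
    """A quadripolar design: 4 of the 8 electrode positions."""

    name: str  # sorted letters, e.g. "acdh"
    electrodes: tuple

    def admissible_configurations(self) -> list[str]:
        """The 4 single and 6 paired configuration names this design offers."""
        singles = [e for e in self.electrodes]
        pairs = ["".join(p) for p in itertools.combinations(self.electrodes, 2)]
        return sorted(singles + pairs)

    def contains(self, config_name: str) -> bool:
        return set(config_name) <= set(self.electrodes)


class VeinGeometryError(RuntimeError):
    """The epicardial vein line is too short for the electrode array."""


def _rotational_frame(coords: VentricularCoordinates):
    """Unit vectors at phi = 0 (anterior) and phi = +90 deg (lateral)."""
    if coords.anterior is None or coords.lateral is None:
        raise ValueError("coordinates carry no rotational frame (recompute UVC)")
    return coords.anterior, coords.lateral


def locate_vein_line(
    mesh: VentricularMesh,
    coords: VentricularCoordinates,
    aha: Aha17Map,
    vein: Vein,
    basal_z: float = 0.8,
    min_length: float = 52.5,
) -> VeinLine:
    """Slice the LV epicardium at the vein's rotational angle.

    Intersects epicardial triangles with the constant-phi half plane,
    interpolating positions and the apicobasal coordinate along crossing
    edges, then orders the crossings from z = ``basal_z`` down toward the
    apex.  ``aha`` is accepted for interface completeness (the vein angles
    are derived from the same segment-centre convention the map uses).
    """
    phi0 = np.deg2rad(vein.angle_deg)
    tris = mesh.surface_triangles[mesh.surface_labels == EPI]
    nodes_all = mesh.node_coordinates
    axis = coords.long_axis
    # orthonormal frame: ant (phi = 0), lat (phi = +90 deg)
    rel_frame = _rotational_frame(coords)
    ant, lat = rel_frame
    u = np.cos(phi0) * ant + np.sin(phi0) * lat  # in-half-plane direction
    w = -np.sin(phi0) * ant + np.cos(phi0) * lat  # half-plane normal
    rel = nodes_all - coords.axis_origin
    s_node = rel @ w
    u_node = rel @ u

    d = s_node[tris]
    near = (u_node[tris] > 0).all(axis=1)  # correct side of the axis
    tris = tris[near]
    d = d[near]
    crossing = (d.min(axis=1) < 0) & (d.max(axis=1) > 0)
    tris = tris[crossing]
    d = d[crossing]

    pts, zs = [], []
    nodes = mesh.node_coordinates
    for (i, j) in ((0, 1), (1, 2), (0, 2)):
        di, dj = d[:, i], d[:, j]
        sel = (di * dj) < 0
        t = di[sel] / (di[sel] - dj[sel])
        a = tris[sel, i]
        b = tris[sel, j]
        pts.append(nodes[a] + t[:, None] * (nodes[b] - nodes[a]))
        zs.append(coords.z[a] + t * (coords.z[b] - coords.z[a]))
    pts = np.concatenate(pts)
    zs = np.concatenate(zs)
    # near the apex pole an edge can straddle the axis; keep only crossings
    # genuinely inside the half plane
    inside = (pts - coords.axis_origin) @ u > 0
    pts, zs = pts[inside], zs[inside]
    if len(pts) < 4:
        raise VeinGeometryError(f"vein {vein.name}: epicardial slice is empty")

    # order along the meridian by axial position (strictly monotone from the
    # base ring to the apex; the uvc z flattens to 0 over the apex cap)
    axial = (pts - coords.axis_origin) @ coords.long_axis
    order = np.argsort(-axial, kind="stable")
    pts, zs = pts[order], zs[order]
    # deduplicate coincident crossings (shared edges appear twice)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts, zs = pts[keep], zs[keep]

    # clip to start at z = basal_z (interpolating the exact start point)
    below = np.flatnonzero(zs <= basal_z)
    if len(below) == 0:
        raise VeinGeometryError(f"vein {vein.name}: no epicardium below z={basal_z}")
    k = below[0]
    if k > 0:
        t = (zs[k - 1] - basal_z) / (zs[k - 1] - zs[k])
        start = pts[k - 1] + t * (pts[k] - pts[k - 1])
        pts = np.concatenate([[start], pts[k:]])
        zs = np.concatenate([[basal_z], zs[k:]])
    else:
        pts, zs = pts[k:], zs[k:]

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    line = VeinLine(vein=vein, points=pts, z=zs, arc=arc)
    if line.length < min_length:
        raise VeinGeometryError(
            f"vein {vein.name}: epicardial line is {line.length:.1f} mm, "
            f"shorter than the required {min_length} mm"
        )
    return line


def place_electrodes(
    mesh: VentricularMesh,
    line: VeinLine,
    n: int = 8,
    spacing: float = 7.5,
    basal_z: float = 0.8,
) -> Lead:
    """Place ``n`` electrodes at ``spacing`` mm pitch along the vein line.

    Electrode k sits at arc distance (k-1)*spacing from the basal end and is
    snapped to the nearest epicardial mesh node (ties break to the lowest
    node id).  ``basal_z`` is honoured by the vein line construction.
    """
    span = (n - 1) * spacing
    if line.length < span:
        raise VeinGeometryError(
            f"vein {line.vein.name}: need {span} mm of line, have {line.length:.1f}"
        )
    ideal = np.arange(n) * spacing
    targets = np.stack(
        [np.interp(ideal, line.arc, line.points[:, k]) for k in range(3)], axis=1
    )
    epi_nodes = mesh.surface_nodes(EPI)
    tree = cKDTree(mesh.node_coordinates[epi_nodes])
    _, nearest = tree.query(targets)
    node_ids = epi_nodes[nearest]
    # arc position of each snapped node: project onto the nearest segment
    snapped = mesh.node_coordinates[node_ids]
    a = line.points[:-1]
    b = line.points[1:]
    ab = b - a
    ab2 = np.maximum((ab**2).sum(axis=1), 1e-30)
    ap = snapped[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psj,sj->ps", ap, ab) / ab2[None, :], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d2 = ((proj - snapped[:, None, :]) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    arc_snapped = line.arc[best] + t[np.arange(len(best)), best] * np.sqrt(
        ab2[best]
    )
    return Lead(
        vein=line.vein,
        electrode_nodes=node_ids,
        electrode_labels=tuple(ELECTRODE_LETTERS[:n]),
        arc_positions=arc_snapped,
        ideal_arc=ideal,
    )


def place_rv_electrode(
    mesh: VentricularMesh, coords: VentricularCoordinates, site: str = "APEX"
) -> int:
    """RV pacing electrode node: endocardial RV apex, or septal mid-wall.

    APEX: RV endocardial node with the smallest apicobasal coordinate.
    SEPTAL_MID: septal RV-endocardial node closest to z = 0.5.
    """
    rv_endo = mesh.surface_nodes(RV_ENDO)
    if len(rv_endo) == 0:
        raise ValueError("mesh has no RV endocardium")
    if site == "APEX":
        return int(rv_endo[np.argmin(coords.z[rv_endo])])
    if site == "SEPTAL_MID":
        septal = _septal_rv_endo_nodes(mesh)
        if len(septal) == 0:
            septal = rv_endo
        return int(septal[np.argmin(np.abs(coords.z[septal] - 0.5))])
    raise ValueError(f"unknown RV site {site!r}; expected APEX or SEPTAL_MID")


def _septal_rv_endo_nodes(mesh: VentricularMesh) -> np.ndarray:
    """RV endocardial nodes on the septum (faces owned by LV elements)."""
    from .coordinates import _surface_owners

    owners = _surface_owners(mesh)
    sel = (mesh.surface_labels == RV_ENDO) & (mesh.element_region[owners] == LV_WALL)
    return np.unique(mesh.surface_triangles[sel])


def enumerate_configurations(lead: Lead, rv_node: int) -> list[PacingConfiguration]:
    """All 8 single and 28 paired LV stimulus sets (36), each with the RV
    electrode, in lexicographic name order."""
    letters = lead.electrode_labels
    names = [l for l in letters] + [
        "".join(c) for c in itertools.combinations(letters, 2)
    ]
    names.sort()
    return [
        PacingConfiguration(
            name=nm, active_lv_electrodes=tuple(nm), rv_electrode=int(rv_node)
        )
        for nm in names
    ]


def enumerate_lead_designs(letters: str = ELECTRODE_LETTERS) -> list[LeadDesign]:
    """All 4-subsets of the 8 electrode positions (70 designs)."""
    return [
        LeadDesign(name="".join(c), electrodes=tuple(c))
        for c in itertools.combinations(letters, 4)
    ]


def designs_covering(config_name: str, designs: Sequence[LeadDesign]) -> list[LeadDesign]:
    """Designs whose 4 electrodes contain the configuration's electrodes."""
    return [d for d in designs if d.contains(config_name)]
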