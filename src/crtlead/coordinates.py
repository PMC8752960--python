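"""Ventricular coordinate fields (UVC role), AHA-17 map and wall thickness.

The apicobasal coordinate z and the transmural coordinate rho come from
linear-FEM Laplace solves on the tetrahedral mesh (z: apex = 0, base = 1 on
the whole biventricular domain; rho: endocardium = 0, epicardium = 1 solved
per ventricular region, with the septal RV-endocardial surface acting as the
outer boundary of the LV solve).  The rotational coordinate phi is the angle
about the LV long axis, zero at the centre of the anterior LV free wall and
increasing toward the lateral wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .anatomy import BASE, EPI, LV_ENDO, LV_WALL, RV_ENDO, RV_WALL, VentricularMesh

__all__ = [
    "VentricularCoordinates",
    "Aha17Map",
    "compute_uvc",
    "map_aha17",
    "compute_wall_thickness",
    "element_gradients",
    "SEGMENT_CENTRE_DEG",
]

LV = 0
RV = 1

# Rotational centres (degrees) of the AHA segments, phi = 0 at the anterior
# free-wall centre, increasing toward the lateral wall.  Basal ring 1-6,
# mid ring 7-12, apical 13-16, apical cap 17.
SEGMENT_CENTRE_DEG = {
    1: 0.0, 2: -60.0, 3: -120.0, 4: 180.0, 5: 120.0, 6: 60.0,
    7: 0.0, 8: -60.0, 9: -120.0, 10: 180.0, 11: 120.0, 12: 60.0,
    13: 0.0, 14: -90.0, 15: 180.0, 16: 90.0,
}

# apicobasal band cut-offs (config-exposed conventions)
APEX_CAP_Z = 0.15
APICAL_Z = 0.45
MID_Z = 0.72


@dataclass
class VentricularCoordinates:
    """Per-node coordinate fields on a biventricular mesh."""

    z: np.ndarray  # apicobasal in [0, 1], 0 apex, 1 base
    rho: np.ndarray  # transmural in [0, 1], 0 endo, 1 epi
    phi: np.ndarray  # rotational in (-pi, pi]
    nu: np.ndarray  # ventricle label per node, LV / RV
    long_axis: np.ndarray = None  # unit vector, apex -> base
    axis_origin: np.ndarray = None  # point on the axis (base centroid)
    anterior: np.ndarray = None  # unit vector at phi = 0
    lateral: np.ndarray = None  # unit vector at phi = +90 deg


@dataclass
class Aha17Map:
    """17-segment AHA labelling of the LV nodes (0 for non-LV nodes)."""

    segment: np.ndarray  # per-node int, 1..17 on LV nodes, 0 elsewhere


class LabellingError(ValueError):
    """A required surface label is missing from the mesh."""


def _stiffness_matrix(nodes: np.ndarray, tets: np.ndarray) -> csr_matrix:
    """P1 FEM stiffness matrix for the Laplace operator."""
    p = nodes[tets]
    # gradients of barycentric shape functions
    v0 = p[:, 0]
    J = p[:, 1:] - v0[:, None, :]  # (n, 3, 3) rows are edge vectors
    Jinv = np.linalg.inv(J)  # columns give grad lambda_i, i = 1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    vol = np.abs(np.einsum("ij,ij->i", J[:, 0], np.cross(J[:, 1], J[:, 2]))) / 6.0
    ke = np.einsum("eid,ejd,e->eij", g, g, vol)
    ii = np.repeat(tets, 4, axis=1).ravel()
    jj = np.tile(tets, (1, 4)).ravel()
    K = coo_matrix((ke.ravel(), (ii, jj)), shape=(len(nodes),) * 2)
    return K.tocsr()


def _solve_laplace(
    K: csr_matrix, dirichlet: dict[int, float], n_nodes: int, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Solve K u = 0 with Dirichlet values; optionally restricted to ``mask`` nodes."""
    u = np.zeros(n_nodes)
    fixed = np.zeros(n_nodes, dtype=bool)
    for nid, val in dirichlet.items():
        fixed[nid] = True
        u[nid] = val
    free = ~fixed
    if mask is not None:
        free &= mask
    idx = np.flatnonzero(free)
    if len(idx) == 0:
        return u
    Kff = K[idx][:, idx]
    rhs = -K[idx][:, np.flatnonzero(fixed)] @ u[np.flatnonzero(fixed)]
    u[idx] = spsolve(Kff.tocsc(), rhs)
    return u


def _relabel_by_height(z: np.ndarray, height: np.ndarray, n_bins: int = 40) -> np.ndarray:
    """Monotone re-labelling of a [0,1] field by the mean height of its
    level sets (endpoints pinned at 0 and 1)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centres = []
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (z > lo) & (z <= hi)
        if sel.any():
            centres.append(0.5 * (lo + hi))
            means.append(height[sel].mean())
    xs = np.concatenate([[0.0], centres, [1.0]])
    ys = np.maximum.accumulate(np.concatenate([[0.0], means, [1.0]]))
    out = np.interp(z, xs, ys)
    out[z == 0.0] = 0.0
    out[z == 1.0] = 1.0
    return np.clip(out, 0.0, 1.0)


def _long_axis(mesh: VentricularMesh):
    """Long axis from the base-plane fit: unit vector apex -> base + base centroid."""
    base_nodes = mesh.surface_nodes(BASE)
    if len(base_nodes) == 0:
        raise LabellingError("mesh has no BASE surface label")
    pb = mesh.node_coordinates[base_nodes]
    centroid = pb.mean(axis=0)
    # direction from the bulk of the myocardium toward the base; more robust
    # against an asymmetric (e.g. RV-crescent) base ring than a plane fit
    axis = centroid - mesh.node_coordinates.mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    return axis, centroid


def compute_uvc(
    mesh: VentricularMesh, anterior_direction=(0.0, 1.0, 0.0)
) -> VentricularCoordinates:
    """Compute UVC-style coordinates on a labelled biventricular mesh.

    ``anterior_direction`` fixes the rotational origin (the anterior LV
    free-wall centre); the synthetic anatomy uses +y.
    """
    for lab, name in ((BASE, "BASE"), (LV_ENDO, "LV_ENDO"), (EPI, "EPI")):
        if not (mesh.surface_labels == lab).any():
            raise LabellingError(f"mesh has no {name} surface label")

    nodes = mesh.node_coordinates
    n = len(nodes)
    K = _stiffness_matrix(nodes, mesh.tetrahedra)
    axis, base_centroid = _long_axis(mesh)

    # --- apicobasal z: Laplace with base = 1, apex cap = 0 ----------------
    axial = (nodes - base_centroid) @ axis  # 0 at base plane, negative toward apex
    extent = -axial.min()
    apex_nodes = np.flatnonzero(axial <= axial.min() + 0.02 * extent)
    dirichlet = {int(i): 1.0 for i in mesh.surface_nodes(BASE)}
    for i in apex_nodes:
        dirichlet[int(i)] = 0.0
    z = np.clip(_solve_laplace(K, dirichlet, n), 0.0, 1.0)
    # The raw harmonic field crowds logarithmically near the (nearly
    # point-like) apex, so equal z-fractions would not be equal apicobasal
    # fractions.  Re-label the level sets monotonically by their mean
    # normalized axial height: the level surfaces keep their Laplace
    # smoothness, but z = 0.33 now means a third of the way up, as the
    # FEC-band and electrode conventions assume.
    height = 1.0 - axial / axial.min()  # 0 at the apex, 1 at the base plane
    z = _relabel_by_height(z, np.clip(height, 0.0, 1.0))

    # --- ventricle label nu (majority of incident element regions) -------
    nu = np.zeros(n, dtype=np.int8)
    counts = np.zeros((n, 2))
    for r, code in ((LV_WALL, LV), (RV_WALL, RV)):
        sel = mesh.element_region == r
        np.add.at(counts[:, code], mesh.tetrahedra[sel].ravel(), 1.0)
    nu[counts[:, RV] > counts[:, LV]] = RV

    # --- transmural rho: per-region Laplace solves ------------------------
    tri_owner = _surface_owners(mesh)
    owner_region = mesh.element_region[tri_owner]
    lv_elems = mesh.element_region == LV_WALL
    rv_elems = mesh.element_region == RV_WALL
    lv_node_mask = np.zeros(n, dtype=bool)
    lv_node_mask[mesh.tetrahedra[lv_elems].ravel()] = True
    rv_node_mask = np.zeros(n, dtype=bool)
    rv_node_mask[mesh.tetrahedra[rv_elems].ravel()] = True

    rho = np.zeros(n)
    # LV: endo = 0; epi and septal RV-endo = 1
    dir_lv: dict[int, float] = {}
    for i in mesh.surface_nodes(LV_ENDO):
        dir_lv[int(i)] = 0.0
    outer_lv = (mesh.surface_labels == EPI) | (
        (mesh.surface_labels == RV_ENDO) & (owner_region == LV_WALL)
    )
    for i in np.unique(mesh.surface_triangles[outer_lv]):
        if lv_node_mask[i]:
            dir_lv[int(i)] = 1.0
    rho_lv = _solve_laplace(K, dir_lv, n, mask=lv_node_mask)

    # RV free wall: endo = 0, epi = 1
    rv_endo_tris = (mesh.surface_labels == RV_ENDO) & (owner_region == RV_WALL)
    dir_rv: dict[int, float] = {}
    for i in np.unique(mesh.surface_triangles[rv_endo_tris]):
        dir_rv[int(i)] = 0.0
    epi_tris = mesh.surface_labels == EPI
    for i in np.unique(mesh.surface_triangles[epi_tris]):
        if rv_node_mask[i] and int(i) not in dir_rv:
            dir_rv[int(i)] = 1.0
    if dir_rv:
        rho_rv = _solve_laplace(K, dir_rv, n, mask=rv_node_mask)
    else:
        rho_rv = np.zeros(n)

    rho[lv_node_mask] = rho_lv[lv_node_mask]
    rho[rv_node_mask & (nu == RV)] = rho_rv[rv_node_mask & (nu == RV)]
    rho = np.clip(rho, 0.0, 1.0)

    # --- rotational phi ----------------------------------------------------
    ant = np.asarray(anterior_direction, dtype=float)
    ant = ant - (ant @ axis) * axis
    if np.linalg.norm(ant) < 1e-9:
        raise ValueError("anterior_direction is parallel to the long axis")
    ant /= np.linalg.norm(ant)
    lat = np.cross(ant, axis)  # increases toward the lateral wall
    rel = nodes - base_centroid
    phi = np.arctan2(rel @ lat, rel @ ant)

    return VentricularCoordinates(
        z=z, rho=rho, phi=phi, nu=nu, long_axis=axis, axis_origin=base_centroid,
        anterior=ant, lateral=lat,
    )


def _surface_owners(mesh: VentricularMesh) -> np.ndarray:
    """Owning element index of each boundary triangle."""
    face_order = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    tets = mesh.tetrahedra
    n = np.int64(mesh.n_nodes)

    def face_keys(faces):
        s = np.sort(faces, axis=1).astype(np.int64)
        return (s[:, 0] * n + s[:, 1]) * n + s[:, 2]

    all_keys = np.concatenate([face_keys(tets[:, idx]) for idx in face_order])
    owner = np.tile(np.arange(len(tets), dtype=np.int64), 4)
    order = np.argsort(all_keys, kind="stable")
    sk, so = all_keys[order], owner[order]
    pos = np.searchsorted(sk, face_keys(mesh.surface_triangles))
    return so[pos]


def map_aha17(coords: VentricularCoordinates) -> Aha17Map:
    """Assign every LV node to one of the 17 AHA segments from (z, phi)."""
    z = coords.z
    phi_deg = np.rad2deg(coords.phi)
    seg = np.zeros(len(z), dtype=np.int64)
    lv = coords.nu == LV

    def sector(phi, centres):
        width = 360.0 / len(centres)
        out = np.zeros(len(phi), dtype=np.int64)
        for s, c in centres.items():
            d = (phi - c + 180.0) % 360.0 - 180.0
            out[np.abs(d) <= width / 2] = s
        return out

    basal = {k: SEGMENT_CENTRE_DEG[k] for k in range(1, 7)}
    mid = {k: SEGMENT_CENTRE_DEG[k] for k in range(7, 13)}
    apical = {k: SEGMENT_CENTRE_DEG[k] for k in range(13, 17)}

    cap = lv & (z <= APEX_CAP_Z)
    ap = lv & (z > APEX_CAP_Z) & (z <= APICAL_Z)
    md = lv & (z > APICAL_Z) & (z <= MID_Z)
    bs = lv & (z > MID_Z)
    seg[cap] = 17
    seg[ap] = sector(phi_deg[ap], apical)
    seg[md] = sector(phi_deg[md], mid)
    seg[bs] = sector(phi_deg[bs], basal)
    # boundary nodes exactly on a sector edge fall to the lower segment id by
    # the <= rule above; nothing is left unassigned on the LV
    return Aha17Map(segment=seg)


def element_gradients(mesh: VentricularMesh, field: np.ndarray) -> np.ndarray:
    """Per-element gradient of a nodal P1 field."""
    p = mesh.node_coordinates[mesh.tetrahedra]
    J = p[:, 1:] - p[:, 0][:, None, :]
    Jinv = np.linalg.inv(J)
    d = field[mesh.tetrahedra[:, 1:]] - field[mesh.tetrahedra[:, 0]][:, None]
    # grad f = sum_i (f_i - f_0) * grad(lambda_i), grad(lambda_i) = i-th column of Jinv
    return np.einsum("eij,ej->ei", Jinv, d)


def compute_wall_thickness(
    mesh: VentricularMesh, coords: VentricularCoordinates
) -> np.ndarray:
    """Per-element LV wall thickness (mm) along the transmural direction.

    For each LV element, rays are cast from the centroid along -grad(rho)
    to the endocardium and along +grad(rho) to the outer LV boundary
    (epicardium, or the septal RV endocardium); thickness is the summed hit
    distance.  Misses (e.g. rays leaving through the base) fall back to
    nearest-surface-point distances.  RV elements get NaN.
    """
    grad = element_gradients(mesh, coords.rho)
    lv = mesh.element_region == LV_WALL
    gnorm = np.linalg.norm(grad, axis=1)
    if (gnorm[lv] < 1e-12).any():
        raise ValueError("zero transmural gradient on an LV element")
    d_hat = grad / np.maximum(gnorm, 1e-300)[:, None]
    cent = mesh.element_centroids()

    owner_region = mesh.element_region[_surface_owners(mesh)]
    endo_sel = mesh.surface_labels == LV_ENDO
    outer_sel = (mesh.surface_labels == EPI) | (
        (mesh.surface_labels == RV_ENDO) & (owner_region == LV_WALL)
    )
    endo_tris = mesh.surface_triangles[endo_sel]
    outer_tris = mesh.surface_triangles[outer_sel]

    idx = np.flatnonzero(lv)
    # search radius from the Laplace thickness estimate 1/|grad rho|
    radius = 1.3 * float(np.percentile(1.0 / gnorm[idx], 99)) + 3.0
    t_endo = _ray_distances(cent[idx], -d_hat[idx], mesh.node_coordinates, endo_tris, radius)
    t_outer = _ray_distances(cent[idx], d_hat[idx], mesh.node_coordinates, outer_tris, radius)

    thickness = np.full(mesh.n_elements, np.nan)
    thickness[idx] = t_endo + t_outer
    return thickness


def _mt_raycast(o, d, v0, e1, e2):
    """Moller-Trumbore: nearest positive hit distance of rays (o, d) vs tris."""
    pvec = np.cross(d[:, None, :], e2[None, :, :])  # (r, t, 3)
    det = np.einsum("tj,rtj->rt", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = o[:, None, :] - v0[None, :, :]
    u = np.einsum("rtj,rtj->rt", tvec, pvec) * inv
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rj,rtj->rt", d, qvec) * inv
    t = np.einsum("tj,rtj->rt", e2, qvec) * inv
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > 1e-9)
    return np.where(hit, t, np.inf).min(axis=1)


def _ray_distances(origins, directions, nodes, tris, radius=None, chunk=256):
    """Nearest forward ray-triangle intersection distance per origin.

    Chunks of (spatially contiguous) rays are tested against the triangles
    whose centroids lie within ``radius`` of the chunk, with a full-surface
    retry and finally a nearest-surface-vertex fallback for misses.
    """
    from scipy.spatial import cKDTree

    v0 = nodes[tris[:, 0]]
    e1 = nodes[tris[:, 1]] - v0
    e2 = nodes[tris[:, 2]] - v0
    out = np.full(len(origins), np.inf)
    tree = None
    if radius is not None:
        tri_cent = (nodes[tris[:, 0]] + nodes[tris[:, 1]] + nodes[tris[:, 2]]) / 3.0
        tree = cKDTree(tri_cent)
        tri_size = np.sqrt(np.maximum(np.linalg.norm(np.cross(e1, e2), axis=1), 0.0))
        radius = radius + float(np.median(tri_size))
    for s in range(0, len(origins), chunk):
        o = origins[s : s + chunk]
        d = directions[s : s + chunk]
        if tree is not None:
            cand_lists = tree.query_ball_point(o, radius)
            cand = np.unique(np.concatenate([np.asarray(c, dtype=int) for c in cand_lists]) if len(cand_lists) else np.array([], dtype=int))
            if len(cand) == 0:
                continue
            out[s : s + chunk] = _mt_raycast(o, d, v0[cand], e1[cand], e2[cand])
        else:
            out[s : s + chunk] = _mt_raycast(o, d, v0, e1, e2)
    miss = ~np.isfinite(out)
    if miss.any() and radius is not None:
        out[miss] = _ray_distances(origins[miss], directions[miss], nodes, tris, None)
        miss = ~np.isfinite(out)
    if miss.any():
        surf = cKDTree(nodes[np.unique(tris)])
        out[miss] = surf.query(origins[miss])[0]
    return out
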