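"""Anisotropic eikonal conduction model.

Solves sqrt(grad(T)^T V grad(T)) = 1 for the first-arrival activation time T
on a tetrahedral mesh, where V is a per-element squared-velocity tensor
((mm/ms)^2).  Plain myocardium is transversely isotropic around the fibre
direction (along-fibre speed cv_fibre, cross-fibre k_xf * cv_fibre); a fast
endocardial conduction (FEC) layer one element thick emulates the Purkinje
system with isotropic speed k_fec * cv_fibre over the apical fraction
``fec_extent`` of the endocardium; scar elements are inactive and never
traversed.

The solver performs locally exact face updates (the characteristic entering
each node through the opposite face of every incident tetrahedron, with
edge/vertex fallbacks) iterated to a fixed point, seeded with an edge-graph
Dijkstra upper bound so only metrication corrections remain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .anatomy import LV_ENDO, LV_WALL, RV_ENDO, VentricularMesh

__all__ = [
    "ConductionParameters",
    "VelocityField",
    "ActivationMap",
    "mark_fec_layer",
    "mark_scar",
    "build_velocity_field",
    "solve_eikonal",
    "dijkstra_oracle",
    "EikonalSolver",
]


@dataclass(frozen=True)
class ConductionParameters:
    """Conduction velocity parameters (velocities in mm/ms = m/s).

    Defaults: cv_fibre 0.5, cross-fibre ratio k_xf 0.6, FEC speed-up
    k_fec 5 over the apical third of the endocardium.  ``scar_threshold``
    (mm) blocks conduction in LV elements thinner than the threshold;
    ``None`` disables scar.
    """

    cv_fibre: float = 0.5
    k_xf: float = 0.6
    k_fec: float = 5.0
    fec_extent: float = 0.33
    scar_threshold: Optional[float] = None
    fec_in_rv: bool = True  # FEC on both endocardia (config-exposed)
    scar_overrides_fec: bool = True

    def validate(self) -> None:
        if self.cv_fibre <= 0:
            raise ValueError("cv_fibre must be positive")
        if not 0 < self.k_xf <= 1:
            raise ValueError("k_xf must lie in (0, 1]")
        if self.k_fec < 1:
            raise ValueError("k_fec must be >= 1")
        if not 0 <= self.fec_extent <= 1:
            raise ValueError("fec_extent must lie in [0, 1]")
        if self.scar_threshold is not None and self.scar_threshold < 0:
            raise ValueError("scar_threshold must be non-negative")

    def override(self, **kwargs) -> "ConductionParameters":
        p = replace(self, **kwargs)
        p.validate()
        return p


@dataclass
class VelocityField:
    """Per-element squared-velocity tensors and activity mask."""

    tensor: np.ndarray  # (n_elem, 3, 3) symmetric PSD, (mm/ms)^2
    active: np.ndarray  # (n_elem,) bool, False for scar


@dataclass
class ActivationMap:
    """Per-node activation times (ms); unreached nodes are +inf."""

    times: np.ndarray
    sources: tuple  # ((node, onset), ...)


def _endocardium_adjacent(mesh: VentricularMesh, include_rv: bool) -> np.ndarray:
    """Elements owning at least one endocardial boundary face."""
    sel = mesh.surface_labels == LV_ENDO
    if include_rv:
        sel |= mesh.surface_labels == RV_ENDO
    n = np.int64(mesh.n_nodes)

    def face_keys(faces):
        s = np.sort(faces, axis=1).astype(np.int64)
        return (s[:, 0] * n + s[:, 1]) * n + s[:, 2]

    endo_keys = face_keys(mesh.surface_triangles[sel])
    face_order = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    tets = mesh.tetrahedra
    mask = np.zeros(mesh.n_elements, dtype=bool)
    for fo in face_order:
        mask |= np.isin(face_keys(tets[:, fo]), endo_keys)
    return mask


def mark_fec_layer(
    mesh: VentricularMesh, coords, fec_extent: float, include_rv: bool = True
) -> np.ndarray:
    """One-element-thick FEC mask: endocardium-adjacent elements whose mean
    apicobasal coordinate is at most ``fec_extent`` (0.33 = apical third,
    1.0 = the whole endocardium)."""
    if not 0 <= fec_extent <= 1:
        raise ValueError("fec_extent must lie in [0, 1]")
    if fec_extent == 0:
        return np.zeros(mesh.n_elements, dtype=bool)
    adj = _endocardium_adjacent(mesh, include_rv)
    z_elem = coords.z[mesh.tetrahedra].mean(axis=1)
    return adj & (z_elem <= fec_extent)


def mark_scar(thickness: np.ndarray, threshold: float, element_region=None) -> np.ndarray:
    """Scar mask: LV elements with wall thickness below ``threshold`` mm.

    ``thickness`` is NaN on RV elements (see compute_wall_thickness), which
    never mark; passing ``element_region`` makes the LV restriction explicit.
    """
    if threshold < 0:
        raise ValueError("scar threshold must be non-negative")
    with np.errstate(invalid="ignore"):
        mask = np.asarray(thickness) < threshold
    if element_region is not None:
        mask &= np.asarray(element_region) == LV_WALL
    return mask


def build_velocity_field(
    mesh: VentricularMesh,
    params: ConductionParameters,
    fec_mask: Optional[np.ndarray] = None,
    scar_mask: Optional[np.ndarray] = None,
) -> VelocityField:
    """Assemble per-element squared-velocity tensors.

    Myocardium: V = cv_f^2 f f^T + (k_xf cv_f)^2 (I - f f^T).
    FEC elements: isotropic V = (k_fec cv_f)^2 I (overrides anisotropy).
    Scar elements: inactive (by default even if also FEC).
    """
    params.validate()
    f = mesh.element_fibre
    norms = np.linalg.norm(f, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("element fibres must be unit vectors")
    n = mesh.n_elements
    cv_l = params.cv_fibre
    cv_t = params.k_xf * params.cv_fibre
    eye = np.eye(3)
    ff = np.einsum("ei,ej->eij", f, f)
    V = cv_l**2 * ff + cv_t**2 * (eye[None] - ff)
    if fec_mask is not None and fec_mask.any():
        V[fec_mask] = (params.k_fec * cv_l) ** 2 * eye
    active = np.ones(n, dtype=bool)
    if scar_mask is not None:
        active &= ~np.asarray(scar_mask, dtype=bool)
    return VelocityField(tensor=V, active=active)


class EikonalSolver:
    """Reusable eikonal solver for one (mesh, velocity field) pair.

    Precomputes the per-tetrahedron local-update coefficients once, so many
    pacing configurations on the same heart amortize the setup cost.
    """

    def __init__(self, mesh: VentricularMesh, field: VelocityField):
        self.mesh = mesh
        self.field = field
        self.n_nodes = mesh.n_nodes
        act = np.flatnonzero(field.active)
        self._active_elems = act
        tets = mesh.tetrahedra[act]
        self._tets = tets
        nodes = mesh.node_coordinates
        M = np.linalg.inv(field.tensor[act])  # slowness-squared tensors

        # candidate list: one per (tet, vertex) = face update target
        face_of_vertex = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        tv, ta, tb, tc = [], [], [], []
        Ms = []
        for v_loc in range(4):
            a, b, c = face_of_vertex[v_loc]
            tv.append(tets[:, v_loc])
            ta.append(tets[:, a])
            tb.append(tets[:, b])
            tc.append(tets[:, c])
            Ms.append(M)
        self.cand_elem = np.tile(np.arange(len(act)), 4)
        self.v = np.concatenate(tv)
        self.a = np.concatenate(ta)
        self.b = np.concatenate(tb)
        self.c = np.concatenate(tc)
        M4 = np.concatenate(Ms, axis=0)

        xa, xb, xc, xv = nodes[self.a], nodes[self.b], nodes[self.c], nodes[self.v]
        d1 = xb - xa
        d2 = xc - xa
        bvec = xv - xa

        def mdot(u, w):
            return np.einsum("ei,eij,ej->e", u, M4, w)

        # face-interior solve coefficients
        q11, q12, q22 = mdot(d1, d1), mdot(d1, d2), mdot(d2, d2)
        det = q11 * q22 - q12 * q12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        self.Qi = np.stack([q22 / det, -q12 / det, q11 / det], axis=1)  # inv entries
        self.r1, self.r2 = mdot(d1, bvec), mdot(d2, bvec)
        self.bMb = mdot(bvec, bvec)
        self.rQir = (
            self.Qi[:, 0] * self.r1**2
            + 2 * self.Qi[:, 1] * self.r1 * self.r2
            + self.Qi[:, 2] * self.r2**2
        )

        # edge solves: edges (a,b), (a,c), (b,c); base vertex first
        e_d = [d1, d2, xc - xb]
        e_b = [bvec, bvec, xv - xb]
        self.e_q = np.stack([mdot(d, d) for d in e_d], axis=1)
        self.e_r = np.stack([mdot(d, b_) for d, b_ in zip(e_d, e_b)], axis=1)
        self.e_bb = np.stack([mdot(b_, b_) for b_ in e_b], axis=1)

        # vertex fallbacks: |xv - x|_M from each face vertex
        self.L = np.stack(
            [np.sqrt(self.bMb), np.sqrt(mdot(xv - xb, xv - xb)), np.sqrt(mdot(xv - xc, xv - xc))],
            axis=1,
        )

        # node -> candidate incidence for active-set sweeps
        order = np.argsort(self.a, kind="stable")
        self._by_a = order
        self._elem_of_node = self._build_node_elem_map()
        self._graph = None
        self._cache: dict[int, np.ndarray] = {}
        self.active_node_mask = np.zeros(self.n_nodes, dtype=bool)
        self.active_node_mask[self._tets.ravel()] = True

    def _build_node_elem_map(self):
        from scipy.sparse import coo_matrix as coo

        e = np.repeat(np.arange(len(self._tets)), 4)
        n = self._tets.ravel()
        return coo(
            (np.ones(len(e), dtype=bool), (n, e)),
            shape=(self.n_nodes, len(self._tets)),
        ).tocsr()

    # ---- edge graph (shared with the Dijkstra oracle) --------------------
    def edge_graph(self):
        """Sparse symmetric edge graph with weights sqrt(e^T mean(V)^-1 e)."""
        if self._graph is not None:
            return self._graph
        tets = self._tets
        V = self.field.tensor[self._active_elems]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        i = np.concatenate([tets[:, p0] for p0, _ in pairs])
        j = np.concatenate([tets[:, p1] for _, p1 in pairs])
        Vrep = np.tile(V, (6, 1, 1))
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        key = lo * self.n_nodes + hi
        uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
        Vsum = np.zeros((len(uniq), 3, 3))
        np.add.at(Vsum, inv, Vrep)
        Vmean = Vsum / counts[:, None, None]
        ui = (uniq // self.n_nodes).astype(np.int64)
        uj = (uniq % self.n_nodes).astype(np.int64)
        e = self.mesh.node_coordinates[uj] - self.mesh.node_coordinates[ui]
        Minv = np.linalg.inv(Vmean)
        w = np.sqrt(np.einsum("ei,eij,ej->e", e, Minv, e))
        g = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([ui, uj]), np.concatenate([uj, ui]))),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()
        self._graph = g
        return g

    def _dijkstra_times(self, sources) -> np.ndarray:
        g = self.edge_graph()
        idx = [s for s, _ in sources]
        dist = _csgraph_dijkstra(g, indices=idx)
        dist = dist + np.array([onset for _, onset in sources])[:, None]
        return dist.min(axis=0)

    def _check_sources(self, sources):
        if not sources:
            raise ValueError("at least one source is required")
        for s, onset in sources:
            if onset < 0:
                raise ValueError("source onsets must be >= 0")
            if not self.active_node_mask[s]:
                raise ValueError(f"source node {s} lies on inactive tissue")

    def solve(
        self,
        sources: Sequence[tuple[int, float]],
        tol: float = 1e-6,
        max_sweeps: int = 10000,
        dijkstra_init: bool = True,
    ) -> ActivationMap:
        """First-arrival times from simultaneous sources (node, onset ms).

        Multi-source fields are assembled as the pointwise minimum of the
        single-source solutions (shifted by their onsets): first arrival
        from several stimuli is exactly the minimum of the individual
        first-arrival fields, and combining them this way keeps the
        discrete operator consistent with that identity (a joint sweep
        would suffer O(h) crosstalk where fronts meet).  Single-source
        fields are cached per node, so pacing campaigns that reuse
        electrodes on one heart pay for each electrode once.
        """
        sources = [(int(s), float(o)) for s, o in sources]
        self._check_sources(sources)
        if len(sources) > 1:
            fields = [
                self._single_source_times(s, tol, max_sweeps, dijkstra_init) + o
                for s, o in sources
            ]
            return ActivationMap(
                times=np.minimum.reduce(fields), sources=tuple(sources)
            )
        node, onset = sources[0]
        times = self._single_source_times(node, tol, max_sweeps, dijkstra_init)
        return ActivationMap(times=times + onset, sources=tuple(sources))

    def _single_source_times(
        self, node: int, tol: float, max_sweeps: int, dijkstra_init: bool
    ) -> np.ndarray:
        cached = self._cache.get(node)
        if cached is not None:
            return cached
        sources = [(node, 0.0)]
        src_idx = np.array([node])
        src_onset = np.array([0.0])
        T = np.full(self.n_nodes, np.inf)
        if dijkstra_init:
            T = self._dijkstra_times(sources)
        T[node] = 0.0

        n_cand = len(self.v)
        active = np.arange(n_cand)
        for sweep in range(max_sweeps):
            Ta, Tb, Tc = T[self.a[active]], T[self.b[active]], T[self.c[active]]
            cand = self._local_update(active, Ta, Tb, Tc)
            v = self.v[active]
            Tnew = T.copy()
            np.minimum.at(Tnew, v, cand)
            Tnew[src_idx] = np.minimum(Tnew[src_idx], src_onset)
            # sources stay pinned at their onsets
            Tnew[src_idx] = src_onset
            with np.errstate(invalid="ignore"):
                changed = np.flatnonzero(T - Tnew > tol)
            T = Tnew
            if len(changed) == 0:
                break
            elems = np.unique(self._elem_of_node[changed].indices)
            active = (elems[None, :] + np.arange(4)[:, None] * len(self._tets)).ravel()
        self._cache[node] = T
        return T

    def _local_update(self, sel, Ta, Tb, Tc):
        """Candidate arrival times at self.v[sel] through the opposite face."""
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            t1 = Tb - Ta
            t2 = Tc - Ta
            Qi0, Qi1, Qi2 = self.Qi[sel, 0], self.Qi[sel, 1], self.Qi[sel, 2]
            r1, r2 = self.r1[sel], self.r2[sel]
            # face-interior candidate
            tQit = Qi0 * t1 * t1 + 2 * Qi1 * t1 * t2 + Qi2 * t2 * t2
            denom = 1.0 - tQit
            tau2 = (self.bMb[sel] - self.rQir[sel]) / denom
            tau = np.sqrt(np.maximum(tau2, 0.0))
            lam1 = Qi0 * (r1 - tau * t1) + Qi1 * (r2 - tau * t2)
            lam2 = Qi1 * (r1 - tau * t1) + Qi2 * (r2 - tau * t2)
            eps = 1e-9
            ok = (
                (denom > 0)
                & (tau2 >= 0)
                & (lam1 >= -eps)
                & (lam2 >= -eps)
                & (lam1 + lam2 <= 1 + eps)
                & np.isfinite(Ta)
                & np.isfinite(Tb)
                & np.isfinite(Tc)
            )
            face_c = np.where(ok, Ta + t1 * lam1 + t2 * lam2 + tau, np.inf)

            # edge candidates
            base_T = [Ta, Ta, Tb]
            other_T = [Tb, Tc, Tc]
            edge_c = np.full(len(sel), np.inf)
            for k in range(3):
                q = self.e_q[sel, k]
                r = self.e_r[sel, k]
                bb = self.e_bb[sel, k]
                t = other_T[k] - base_T[k]
                den = 1.0 - t * t / q
                tau2e = (bb - r * r / q) / den
                taue = np.sqrt(np.maximum(tau2e, 0.0))
                lam = (r - taue * t) / q
                oke = (
                    (den > 0)
                    & (tau2e >= 0)
                    & (lam >= -eps)
                    & (lam <= 1 + eps)
                    & np.isfinite(base_T[k])
                    & np.isfinite(other_T[k])
                )
                ce = np.where(oke, base_T[k] + lam * t + taue, np.inf)
                edge_c = np.minimum(edge_c, ce)

            # vertex candidates
            vert_c = np.minimum.reduce(
                [
                    Ta + self.L[sel, 0],
                    Tb + self.L[sel, 1],
                    Tc + self.L[sel, 2],
                ]
            )
        return np.minimum(np.minimum(face_c, edge_c), vert_c)


def solve_eikonal(
    mesh: VentricularMesh,
    field: VelocityField,
    sources: Sequence[tuple[int, float]],
    tol: float = 1e-6,
    max_sweeps: int = 10000,
) -> ActivationMap:
    """Convenience wrapper building a one-shot :class:`EikonalSolver`."""
    return EikonalSolver(mesh, field).solve(sources, tol=tol, max_sweeps=max_sweeps)


def dijkstra_oracle(
    mesh: VentricularMesh, field: VelocityField, sources: Sequence[tuple[int, float]]
) -> ActivationMap:
    """Edge-graph shortest-path activation times.

    Edge weight sqrt(e^T mean(V)^-1 e) with the arithmetic mean of incident
    active element tensors; an upper bound on the eikonal solution that
    tightens under mesh refinement.  Verification reference, not the model.
    """
    solver = EikonalSolver(mesh, field)
    sources = [(int(s), float(o)) for s, o in sources]
    solver._check_sources(sources)
    return ActivationMap(times=solver._dijkstra_times(sources), sources=tuple(sources))
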