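"""Synthetic biventricular anatomy.

Builds idealized tetrahedral biventricular meshes: the LV is a truncated
prolate-ellipsoid shell, the RV a thinner crescent shell wrapped around a
lateral sector of the LV epicardium.  The construction is a structured
(apicobasal x circumferential x transmural) lattice split into tetrahedra,
so it is deterministic and needs no external mesh generator.

Axes convention (mm): the long axis is z (apex down, base up), the anterior
LV free wall faces +y, the RV bulges toward -x.  Units are mm throughout;
velocities elsewhere in the package are mm/ms (numerically equal to m/s).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ShapeParameters",
    "VentricularMesh",
    "CohortSpecification",
    "GeometryError",
    "HF_SHAPE_MEAN",
    "RR_SHAPE_MEAN",
    "generate_biventricular_mesh",
    "sample_cohort",
    "scale_mesh",
    "assign_rule_based_fibres",
    "lv_cavity_volume",
    "truncated_ellipsoid_volume",
]

# element region codes
LV_WALL = 0
RV_WALL = 1
REGION_NAMES = {LV_WALL: "LV_WALL", RV_WALL: "RV_WALL"}

# boundary-triangle label codes
LV_ENDO = 0
RV_ENDO = 1
EPI = 2
BASE = 3
SURFACE_NAMES = {LV_ENDO: "LV_ENDO", RV_ENDO: "RV_ENDO", EPI: "EPI", BASE: "BASE"}


class GeometryError(ValueError):
    """Raised when shape parameters describe an infeasible geometry."""


@dataclass(frozen=True)
class ShapeParameters:
    """Morphological parameters of the idealized biventricular shape.

    All lengths in mm.  ``lv_long_axis`` and ``lv_endo_radius`` are the
    endocardial semi-axes of the LV ellipsoid; ``base_truncation_fraction``
    is the fraction of the long semi-axis cut off at the base (the base
    ring sits at z = (1 - fraction) * lv_long_axis above the centre).
    ``apex_thinning`` linearly thins the LV wall toward the apex (0 keeps
    the wall uniform), mimicking the thin apical wall of dilated hearts.
    """

    lv_long_axis: float = 75.0
    lv_endo_radius: float = 25.0
    lv_wall_thickness: float = 8.0
    rv_wall_thickness: float = 4.0
    rv_lateral_extent: float = 55.0
    base_truncation_fraction: float = 0.3
    target_edge_length: float = 4.0
    apex_thinning: float = 0.25

    def validate(self) -> None:
        lengths = (
            self.lv_long_axis,
            self.lv_endo_radius,
            self.lv_wall_thickness,
            self.rv_wall_thickness,
            self.rv_lateral_extent,
            self.target_edge_length,
        )
        if any(v <= 0 for v in lengths):
            raise GeometryError("all shape lengths must be positive")
        if self.lv_wall_thickness >= self.lv_endo_radius:
            raise GeometryError("lv_wall_thickness must be smaller than lv_endo_radius")
        if not 0.0 < self.base_truncation_fraction < 1.0:
            raise GeometryError("base_truncation_fraction must lie in (0, 1)")
        if not 0.0 <= self.apex_thinning < 1.0:
            raise GeometryError("apex_thinning must lie in [0, 1)")


# Default cohort morphologies.  HF hearts are larger and thinner-walled than
# the reverse-remodelled (healthy-like) ones; cavity volumes land near
# 180 mL (HF) and 120 mL (RR).  These are generator defaults, not claims
# about any measured population.
HF_SHAPE_MEAN = ShapeParameters(
    lv_long_axis=75.0,
    lv_endo_radius=25.0,
    lv_wall_thickness=8.0,
    rv_wall_thickness=4.0,
    rv_lateral_extent=55.0,
)
RR_SHAPE_MEAN = ShapeParameters(
    lv_long_axis=65.0,
    lv_endo_radius=22.0,
    lv_wall_thickness=10.0,
    rv_wall_thickness=4.5,
    rv_lateral_extent=50.0,
)


@dataclass
class VentricularMesh:
    """Tetrahedral biventricular mesh with fibres and labelled surfaces.

    ``surface_triangles`` hold the boundary faces (oriented outward from the
    myocardium); ``surface_labels`` assigns each one of LV_ENDO, RV_ENDO,
    EPI or BASE.  ``node_meta`` carries generator lattice metadata (absent
    on imported meshes).
    """

    node_coordinates: np.ndarray  # (n_nodes, 3) mm
    tetrahedra: np.ndarray  # (n_elem, 4) int
    element_fibre: np.ndarray  # (n_elem, 3) unit vectors
    element_region: np.ndarray  # (n_elem,) int8, LV_WALL / RV_WALL
    surface_triangles: np.ndarray  # (n_tri, 3) int
    surface_labels: np.ndarray  # (n_tri,) int8
    element_volume: np.ndarray = field(default=None)  # (n_elem,) mm^3
    node_meta: Optional[dict] = None

    def __post_init__(self):
        self.node_coordinates = np.asarray(self.node_coordinates, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=np.int64)
        if self.element_volume is None:
            self.element_volume = tet_volumes(self.node_coordinates, self.tetrahedra)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coordinates)

    @property
    def n_elements(self) -> int:
        return len(self.tetrahedra)

    def surface_nodes(self, label: int) -> np.ndarray:
        """Sorted unique node ids lying on boundary triangles with ``label``."""
        return np.unique(self.surface_triangles[self.surface_labels == label])

    def element_centroids(self) -> np.ndarray:
        return self.node_coordinates[self.tetrahedra].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.element_volume.sum())

    def validate(self) -> None:
        vols = tet_volumes(self.node_coordinates, self.tetrahedra)
        if not (vols > 0).all():
            bad = np.flatnonzero(vols <= 0)
            raise ValueError(f"non-positive tetrahedron volumes at elements {bad[:10]}")
        norms = np.linalg.norm(self.element_fibre, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("element fibres must have unit norm")
        if not connected_components(self.tetrahedra, self.n_nodes) == 1:
            raise ValueError("mesh is not a single connected component")


@dataclass(frozen=True)
class CohortSpecification:
    """Specification of a synthetic cohort draw."""

    n_subjects: int
    cohort_type: str  # "HF" or "RR"
    shape_mean: Optional[ShapeParameters] = None
    shape_coefficient_of_variation: float = 0.10
    random_seed: int = 0

    def mean(self) -> ShapeParameters:
        if self.shape_mean is not None:
            return self.shape_mean
        if self.cohort_type == "HF":
            return HF_SHAPE_MEAN
        if self.cohort_type == "RR":
            return RR_SHAPE_MEAN
        raise ValueError(f"unknown cohort_type {self.cohort_type!r}")

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.shape_coefficient_of_variation < 0:
            raise ValueError("coefficient of variation must be >= 0")
        self.mean().validate()


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes (positive for correctly oriented tets)."""
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def connected_components(tets: np.ndarray, n_nodes: int) -> int:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as cc

    i = np.repeat(tets[:, 0], 3)
    j = tets[:, 1:].ravel()
    used = np.unique(tets)
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n_nodes, n_nodes))
    n, labels = cc(adj + adj.T, directed=False)
    # ignore isolated (unused) node ids
    return len(np.unique(labels[used]))


def truncated_ellipsoid_volume(a: float, c: float, z_cut: float) -> float:
    """Volume of the ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 <= 1 below z = z_cut."""
    z = min(z_cut, c)
    return float(np.pi * a * a * ((z + c) - (z**3 + c**3) / (3 * c * c)))


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def generate_biventricular_mesh(
    params: ShapeParameters, seed: int = 0
) -> VentricularMesh:
    """Generate an idealized biventricular tetrahedral mesh.

    The LV endocardium is the ellipsoid with semi-axes
    (lv_endo_radius, lv_endo_radius, lv_long_axis) truncated at the base;
    the epicardium is its offset along the outward surface normal by the
    (apically thinned) wall thickness.  The RV is a crescent shell offset
    further outward across a lateral sector, leaving an RV cavity gap
    between the LV epicardium (septum) and the RV free wall.

    ``seed`` only perturbs nothing here (the construction is deterministic);
    it is accepted for interface symmetry with the cohort sampler.
    """
    params.validate()
    a = params.lv_endo_radius
    c = params.lv_long_axis
    w_lv = params.lv_wall_thickness
    h = params.target_edge_length
    z_base = (1.0 - params.base_truncation_fraction) * c

    if w_lv / max(2, round(w_lv / h)) <= 0:
        raise GeometryError("degenerate wall discretization")

    # lattice resolution
    theta_base = np.arccos(-z_base / c)  # polar angle from apex (-z pole)
    meridian_arc = theta_base * 0.5 * (a + c)  # rough arc estimate
    n_i = max(8, int(round(meridian_arc / h)))  # apicobasal rings (i=0 pole)
    n_j = max(12, int(round(2 * np.pi * (a + w_lv) / h)))  # circumferential
    k_lv = max(2, int(round(w_lv / h)))  # transmural LV layers
    k_rv = max(2, int(round(params.rv_wall_thickness / h)))

    i_idx = np.arange(n_i + 1)
    s = i_idx / n_i  # apicobasal lattice parameter, 0 apex -> 1 base
    theta = s * theta_base
    v = np.arange(n_j) * (2 * np.pi / n_j)  # azimuth, 0 at +x

    # endocardial surface points, rings i=0..n_i
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    ex = a * sin_t[:, None] * np.cos(v)[None, :]
    ey = a * sin_t[:, None] * np.sin(v)[None, :]
    ez = -c * cos_t[:, None] * np.ones_like(v)[None, :]
    endo = np.stack([ex, ey, ez], axis=-1)  # (n_i+1, n_j, 3)

    # outward unit normal of the endocardial ellipsoid
    nrm = endo / np.array([a * a, a * a, c * c])
    nrm /= np.linalg.norm(nrm, axis=-1, keepdims=True)

    # wall thickness per ring (thinner toward apex)
    wall = w_lv * (1.0 - params.apex_thinning * (1.0 - s))  # (n_i+1,)

    # RV crescent bump: lateral sector centred on -x (azimuth pi), tapered
    # near the apex; value in {0} U [0.3, 1] so rim cells stay well-shaped.
    half_width = 0.5 * params.rv_lateral_extent / (a + w_lv)  # radians
    dv = np.abs((v - np.pi + np.pi) % (2 * np.pi) - np.pi)  # |angle - pi|
    ramp_v = _smoothstep((half_width - dv) / (0.35 * half_width))
    ramp_s = _smoothstep((s - 0.12) / 0.18)
    bump = ramp_s[:, None] * ramp_v[None, :]
    bump = np.where(bump > 1e-9, np.maximum(bump, 0.3), 0.0)

    gap = (0.5 * a) * bump  # RV cavity depth beyond the LV epicardium
    w_rv = params.rv_wall_thickness * bump

    # ---- node table ------------------------------------------------------
    # logical layers: k = 0..k_lv (LV wall, endo->epi), then k_lv+1..k_lv+1+k_rv
    # (RV free wall, endo->epi).  Collapsed logical nodes share one id.
    n_layers = k_lv + 1 + k_rv + 1
    node_id = -np.ones((n_i + 1, n_j, n_layers), dtype=np.int64)
    coords: list[np.ndarray] = []
    meta_layer: list[int] = []
    meta_ring: list[int] = []
    meta_gap: list[float] = []

    def radial_offset(i, j, k):
        if k <= k_lv:
            return (k / k_lv) * wall[i]
        m = k - (k_lv + 1)
        return wall[i] + gap[i, j] + (m / k_rv) * w_rv[i, j]

    for k in range(n_layers):
        for i in i_idx:
            if i == 0:
                # pole: one node per layer, RV layers collapse onto epi pole
                kk = min(k, k_lv)
                if k > k_lv:
                    node_id[0, :, k] = node_id[0, 0, kk]
                    continue
                p = endo[0, 0] + radial_offset(0, 0, kk) * nrm[0, 0]
                nid = len(coords)
                coords.append(p)
                meta_layer.append(kk)
                meta_ring.append(0)
                meta_gap.append(0.0)
                node_id[0, :, k] = nid
                continue
            for j in range(n_j):
                if k > k_lv and bump[i, j] == 0.0:
                    node_id[i, j, k] = node_id[i, j, k_lv]
                    continue
                p = endo[i, j] + radial_offset(i, j, k) * nrm[i, j]
                nid = len(coords)
                coords.append(p)
                meta_layer.append(k)
                meta_ring.append(i)
                meta_gap.append(gap[i, j])
                node_id[i, j, k] = nid

    nodes = np.array(coords)
    meta_layer = np.array(meta_layer)
    meta_ring = np.array(meta_ring)
    meta_gap = np.array(meta_gap)

    # ---- tetrahedra via Kuhn subdivision of each lattice hex -------------
    # cell radial layers: LV wall k=0..k_lv-1, RV wall k=k_lv+1..k_lv+k_rv
    cell_layers = list(range(k_lv)) + [k_lv + 1 + m for m in range(k_rv)]
    perms = list(itertools.permutations(range(3)))

    tets = []
    regions = []
    for k in cell_layers:
        region = LV_WALL if k < k_lv else RV_WALL
        for i in range(n_i):
            for j in range(n_j):
                jp = (j + 1) % n_j
                corner = {}
                for di, dj, dk in itertools.product((0, 1), repeat=3):
                    jj = jp if dj else j
                    corner[(di, dj, dk)] = node_id[i + di, jj, k + dk]
                # Kuhn: 6 tets along the main diagonal (0,0,0)->(1,1,1)
                for perm in perms:
                    path = [(0, 0, 0)]
                    cur = [0, 0, 0]
                    for axis in perm:
                        cur[axis] = 1
                        path.append(tuple(cur))
                    tet = [corner[p] for p in path]
                    if len(set(tet)) < 4:
                        continue
                    tets.append(tet)
                    regions.append(region)

    tets = np.array(tets, dtype=np.int64)
    regions = np.array(regions, dtype=np.int8)

    # fix orientation and drop numerically degenerate slivers
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    vols = np.abs(vols)
    keep = vols > 1e-9 * h**3
    tets, regions, vols = tets[keep], regions[keep], vols[keep]

    # ---- boundary faces and labels ---------------------------------------
    tris, labels = _label_boundary(
        nodes, tets, regions, meta_layer, meta_ring, meta_gap, k_lv, n_i
    )

    # placeholder circumferential fibres (refined later from the UVC)
    cent = nodes[tets].mean(axis=1)
    circ = np.stack([-cent[:, 1], cent[:, 0], np.zeros(len(cent))], axis=1)
    bad = np.linalg.norm(circ, axis=1) < 1e-9
    circ[bad] = [1.0, 0.0, 0.0]
    circ /= np.linalg.norm(circ, axis=1, keepdims=True)

    mesh = VentricularMesh(
        node_coordinates=nodes,
        tetrahedra=tets,
        element_fibre=circ,
        element_region=regions,
        surface_triangles=tris,
        surface_labels=labels,
        element_volume=vols,
        node_meta={
            "layer": meta_layer,
            "ring": meta_ring,
            "gap": meta_gap,
            "k_lv": k_lv,
            "n_i": n_i,
            "z_base": z_base,
            "params": params,
        },
    )
    return mesh


def _label_boundary(nodes, tets, regions, meta_layer, meta_ring, meta_gap, k_lv, n_i):
    """Extract outward-oriented boundary triangles and classify them."""
    # faces opposite each vertex, oriented outward for positively oriented tets
    face_order = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([tets[:, idx] for idx in face_order], axis=0)
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key_sorted = key[order]
    dup = np.concatenate(
        [
            (key_sorted[1:] == key_sorted[:-1]).all(axis=1),
            [False],
        ]
    )
    dup[1:] |= (key_sorted[1:] == key_sorted[:-1]).all(axis=1)
    boundary = order[~dup]
    tris = faces[boundary]
    tri_owner = owner[boundary]

    layer = meta_layer[tris]
    ring = meta_ring[tris]
    gmin = meta_gap[tris].min(axis=1)

    labels = np.full(len(tris), EPI, dtype=np.int8)
    labels[(ring == n_i).all(axis=1)] = BASE
    lv_endo = (layer == 0).all(axis=1)
    labels[lv_endo] = LV_ENDO
    # RV endocardium: septal side (layer k_lv faces bounding an open gap) and
    # the free-wall inner surface (layer k_lv+1), both only where gap > 0
    septal = (layer == k_lv).all(axis=1) & (gmin > 1e-9) & (regions[tri_owner] == LV_WALL)
    freewall = (layer == k_lv + 1).all(axis=1) & (regions[tri_owner] == RV_WALL)
    labels[septal | freewall] = RV_ENDO
    labels[(ring == n_i).all(axis=1)] = BASE
    return tris, labels


def lv_cavity_volume(mesh: VentricularMesh) -> float:
    """LV blood-pool volume enclosed by the LV endocardium and the base plane.

    Uses the divergence theorem over the LV_ENDO triangles with the reference
    origin placed on the basal cap plane, so the (flat) cap contributes
    nothing and need not be meshed.
    """
    sel = mesh.surface_labels == LV_ENDO
    tris = mesh.surface_triangles[sel]
    p = mesh.node_coordinates[tris]
    endo_nodes = mesh.node_coordinates[np.unique(tris)]
    origin = np.array(
        [endo_nodes[:, 0].mean(), endo_nodes[:, 1].mean(), endo_nodes[:, 2].max()]
    )
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*A*n (outward of myo)
    cent = p.mean(axis=1) - origin
    flux = np.einsum("ij,ij->i", cent, cross).sum() / 6.0
    return float(abs(flux))


def scale_mesh(mesh: VentricularMesh, factor: float) -> VentricularMesh:
    """Scale the mesh uniformly about its node centroid.

    Element volumes scale by ``factor**3``; fibres, regions and surface
    labels are unchanged.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    centroid = mesh.node_coordinates.mean(axis=0)
    new_nodes = centroid + factor * (mesh.node_coordinates - centroid)
    meta = dict(mesh.node_meta) if mesh.node_meta else None
    return VentricularMesh(
        node_coordinates=new_nodes,
        tetrahedra=mesh.tetrahedra.copy(),
        element_fibre=mesh.element_fibre.copy(),
        element_region=mesh.element_region.copy(),
        surface_triangles=mesh.surface_triangles.copy(),
        surface_labels=mesh.surface_labels.copy(),
        element_volume=mesh.element_volume * factor**3,
        node_meta=meta,
    )


def assign_rule_based_fibres(
    mesh: VentricularMesh,
    coords,
    alpha_endo: float = 60.0,
    alpha_epi: float = -60.0,
) -> VentricularMesh:
    """Assign a rule-based fibre field with a linear transmural helix rotation.

    Per element the local frame is (circumferential, longitudinal, transmural),
    built from the gradients of the transmural (rho) and apicobasal (z)
    coordinates; the fibre lies in the wall-tangent plane at helix angle
    alpha(rho) = alpha_endo + (alpha_epi - alpha_endo) * rho, in degrees.
    """
    from .coordinates import element_gradients

    grad_rho = element_gradients(mesh, coords.rho)
    grad_z = element_gradients(mesh, coords.z)
    gnorm = np.linalg.norm(grad_rho, axis=1)
    bad = gnorm < 1e-12
    if bad.any():
        raise ValueError(
            f"degenerate transmural gradient on elements {np.flatnonzero(bad)[:10]}"
        )
    n_hat = grad_rho / gnorm[:, None]
    ell = grad_z - np.einsum("ij,ij->i", grad_z, n_hat)[:, None] * n_hat
    lnorm = np.linalg.norm(ell, axis=1)
    # elements where apicobasal gradient is (nearly) normal to the wall (apex
    # cap): fall back to any tangent direction
    weak = lnorm < 1e-8
    if weak.any():
        fallback = np.cross(n_hat[weak], np.array([1.0, 0.0, 0.0]))
        fn = np.linalg.norm(fallback, axis=1)
        alt = np.cross(n_hat[weak], np.array([0.0, 1.0, 0.0]))
        fallback[fn < 1e-8] = alt[fn < 1e-8]
        ell[weak] = fallback
        lnorm = np.linalg.norm(ell, axis=1)
    ell_hat = ell / lnorm[:, None]
    c_hat = np.cross(n_hat, ell_hat)

    rho_e = coords.rho[mesh.tetrahedra].mean(axis=1)
    alpha = np.deg2rad(alpha_endo + (alpha_epi - alpha_endo) * rho_e)
    fib = np.cos(alpha)[:, None] * c_hat + np.sin(alpha)[:, None] * ell_hat
    fib /= np.linalg.norm(fib, axis=1, keepdims=True)

    out = VentricularMesh(
        node_coordinates=mesh.node_coordinates,
        tetrahedra=mesh.tetrahedra,
        element_fibre=fib,
        element_region=mesh.element_region,
        surface_triangles=mesh.surface_triangles,
        surface_labels=mesh.surface_labels,
        element_volume=mesh.element_volume,
        node_meta=mesh.node_meta,
    )
    return out


def sample_cohort(spec: CohortSpecification) -> list[VentricularMesh]:
    """Draw ``n_subjects`` meshes with lognormal-ish morphological variability.

    Per-subject seeds derive deterministically from ``spec.random_seed`` via
    numpy SeedSequence spawning, so cohorts are exactly reproducible.
    """
    spec.validate()
    mean = spec.mean()
    cv = spec.shape_coefficient_of_variation
    meshes = []
    for i in range(spec.n_subjects):
        ss = np.random.SeedSequence(spec.random_seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        draw = {}
        for name in (
            "lv_long_axis",
            "lv_endo_radius",
            "lv_wall_thickness",
            "rv_wall_thickness",
            "rv_lateral_extent",
        ):
            mu = getattr(mean, name)
            # lognormal keeps lengths positive at any CV
            sigma = np.sqrt(np.log1p(cv * cv))
            draw[name] = float(mu * np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        params = replace(mean, **draw)
        # guard the wall-vs-radius invariant under extreme draws
        if params.lv_wall_thickness >= params.lv_endo_radius:
            params = replace(
                params, lv_wall_thickness=0.45 * params.lv_endo_radius
            )
        meshes.append(generate_biventricular_mesh(params, seed=i))
    return meshes


def cohort_manifest(spec: CohortSpecification, meshes: Sequence[VentricularMesh]) -> dict:
    """JSON-serializable manifest of a sampled cohort."""
    subjects = []
    for i, m in enumerate(meshes):
        p = m.node_meta["params"] if m.node_meta else None
        subjects.append(
            {
                "id": f"{spec.cohort_type}{i + 1:02d}",
                "seed": i,
                "n_nodes": int(m.n_nodes),
                "n_elements": int(m.n_elements),
                "shape": None if p is None else {
                    k: getattr(p, k) for k in ShapeParameters.__dataclass_fields__
                },
            }
        )
    return {
        "cohort_type": spec.cohort_type,
        "n_subjects": spec.n_subjects,
        "random_seed": spec.random_seed,
        "coefficient_of_variation": spec.shape_coefficient_of_variation,
        "subjects": subjects,
    }


def box_tet_mesh(
    lengths=(10.0, 10.0, 10.0), edge: float = 1.0, fibre=(1.0, 0.0, 0.0)
) -> VentricularMesh:
    """Structured tetrahedral box mesh for solver verification.

    The box spans [0, L] per axis with a uniform fibre direction; faces are
    labelled LV_ENDO (x = 0), BASE (z = max) and EPI elsewhere so the mesh
    satisfies the container invariants.
    """
    L = np.asarray(lengths, dtype=float)
    n = np.maximum(1, np.round(L / edge).astype(int))
    axes = [np.linspace(0, L[d], n[d] + 1) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (n[1] + 1) + j) * (n[2] + 1) + k

    perms = list(itertools.permutations(range(3)))
    tets = []
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                corner = {
                    (a, b, c): nid(i + a, j + b, k + c)
                    for a, b, c in itertools.product((0, 1), repeat=3)
                }
                for perm in perms:
                    path = [(0, 0, 0)]
                    cur = [0, 0, 0]
                    for ax in perm:
                        cur[ax] = 1
                        path.append(tuple(cur))
                    tets.append([corner[p] for p in path])
    tets = np.array(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()

    face_order = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([tets[:, idx] for idx in face_order], axis=0)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    ks = key[order]
    eq_next = np.zeros(len(ks), dtype=bool)
    eq_next[:-1] = (ks[1:] == ks[:-1]).all(axis=1)
    eq_prev = np.zeros(len(ks), dtype=bool)
    eq_prev[1:] = eq_next[:-1]
    tris = faces[order[~(eq_next | eq_prev)]]
    labels = np.full(len(tris), EPI, dtype=np.int8)
    p = nodes[tris]
    labels[(np.abs(p[:, :, 0]) < 1e-9).all(axis=1)] = LV_ENDO
    labels[(np.abs(p[:, :, 2] - L[2]) < 1e-9).all(axis=1)] = BASE

    fib = np.tile(np.asarray(fibre, dtype=float), (len(tets), 1))
    fib /= np.linalg.norm(fib, axis=1, keepdims=True)
    return VentricularMesh(
        node_coordinates=nodes,
        tetrahedra=tets,
        element_fibre=fib,
        element_region=np.zeros(len(tets), dtype=np.int8),
        surface_triangles=tris,
        surface_labels=labels,
    )
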