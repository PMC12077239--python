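"""Structured tetrahedral meshing of a labelled voxel volume.

Bone voxels are grouped into cubic cells — fine cells (edge ``fine_edge_mm``)
inside a margin-expanded bounding box of the sclerotic/lytic regions and
wherever a coarse cell is only partially filled with bone, coarse cells
(edge ``coarse_edge_mm``) elsewhere — and each cell is split into
tetrahedra.  Uniform zones use the Kuhn (Freudenthal) 6-tet decomposition,
which is conforming across identical neighbouring cells.  A one-cell
transition layer of "fan" cells joins the two zones conformally: each fan
cell is tetrahedralized by connecting its centre to a triangulation of its
boundary whose faces are triangulated by a global rule (fine grid against
fine neighbours, centre-fan where an edge is subdivided, Kuhn diagonal
otherwise), so any two cells sharing a face produce the identical face
triangulation.

Cell edges must be commensurate: ``fine_edge_mm`` an integer multiple of the
(isotropic) voxel spacing and ``coarse_edge_mm`` an integer multiple of
``fine_edge_mm``.  Partial *fine* cells at the bone boundary are dropped, so
when ``fine_edge_mm`` equals the voxel spacing (the phantom default) the tet
volumes sum exactly to the bone-mask volume.

Element density is the mean per-voxel ash density of the cell's voxels
(element-wise heterogeneous material) and the element region is the
majority voxel label, with lytic winning ties over sclerotic over the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import ndimage

from .calibration import (
    DEFAULT_CURVE,
    DEFAULT_LAW,
    CalibrationCurve,
    DensityModulusLaw,
    hu_to_rho_ct,
    rho_ct_to_rho_ash,
)
from .errors import DegenerateGeometryError, InvalidInputError
from .image import STRUCT_26, AnatomicalFrame, Label, LabelVolume, VoxelImage

__all__ = [
    "TetrahedralMesh",
    "PsgStripSpec",
    "LoadPatchSpec",
    "voxels_to_tets",
    "tag_boundary_sets",
]


@dataclass
class TetrahedralMesh:
    """Linear tetrahedral mesh with named boundary sets and element data."""

    nodes: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (M, 4) node indices, positively oriented
    element_region: np.ndarray  # (M,) Label values
    element_rho_ash: np.ndarray  # (M,) g/cm^3
    surface_facets: np.ndarray  # (F, 3) node indices, outward oriented
    facet_owner: np.ndarray  # (F,) owning tet index
    fine_edge_mm: float
    coarse_edge_mm: float
    node_sets: dict = field(default_factory=dict)
    facet_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        d = p[:, 1:] - p[:, :1]
        return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    def facet_vertices(self) -> np.ndarray:
        return self.nodes[self.surface_facets]

    def facet_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Outward unit normals and areas of the boundary facets."""
        v = self.facet_vertices()
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        areas = 0.5 * np.linalg.norm(cr, axis=1)
        normals = cr / np.linalg.norm(cr, axis=1)[:, None]
        return normals, areas

    def facet_centroids(self) -> np.ndarray:
        return self.facet_vertices().mean(axis=1)


@dataclass(frozen=True)
class PsgStripSpec:
    """Plane through the parasagittal groove plus an optional axial bound.

    The strip used for strain comparison is the set of boundary facets
    whose centroid lies within half the strip width of this plane; when
    ``max_distal_distance_mm`` is set, facets farther than that from the
    distal extreme (along the long axis) are excluded, restricting the
    strip to the condylar cap.
    """

    point_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    max_distal_distance_mm: float | None = None

    def unit_normal(self) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class LoadPatchSpec:
    """Geometric definition of the loaded palmar patch.

    Either the permissive whole-boundary spec (every non-proximal boundary
    facet) or a spherical patch: facets whose centroid lies within
    ``radius_mm`` of ``center_mm`` and whose outward normal aligns with
    ``direction`` to at least ``min_normal_dot``.
    """

    whole_boundary: bool = False
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    direction: tuple[float, float, float] | None = None
    min_normal_dot: float = 0.2


# ---------------------------------------------------------------------------
# Kuhn decomposition templates (unit cube, positively oriented)


def _unit_kuhn_templates() -> list[np.ndarray]:
    eye = np.eye(3, dtype=np.int64)
    tets = []
    for perm in permutations(range(3)):
        p0 = np.zeros(3, dtype=np.int64)
        p1 = p0 + eye[perm[0]]
        p2 = p1 + eye[perm[1]]
        p3 = np.ones(3, dtype=np.int64)
        verts = np.array([p0, p1, p2, p3])
        d = verts[1:] - verts[0]
        if np.linalg.det(d.astype(float)) < 0:
            verts = verts[[0, 2, 1, 3]]
        tets.append(verts)
    return tets


_KUHN = _unit_kuhn_templates()

# local-face triangulation of a unit square (u, v in {0, 1}):
# diagonal from (0,0) to (1,1); matches the trace of the Kuhn decomposition
# on every cube face, for both cells sharing the face.
_FACE_TRIS = (((0, 0), (1, 0), (1, 1)), ((0, 0), (1, 1), (0, 1)))


class _NodeBook:
    """Deduplicates lattice nodes (integer coords in units of fine_edge/2)."""

    def __init__(self) -> None:
        self._ids: dict[tuple[int, int, int], int] = {}
        self.coords: list[tuple[int, int, int]] = []

    def __call__(self, p) -> int:
        key = (int(p[0]), int(p[1]), int(p[2]))
        nid = self._ids.get(key)
        if nid is None:
            nid = len(self.coords)
            self._ids[key] = nid
            self.coords.append(key)
        return nid


def _block_reduce_labels(lab: np.ndarray, bs: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (bs^3) majority label with LYS > SCL > TRAB > CORTEX
    tie-break, and per-block bone-voxel count."""
    s = lab.shape
    blocks = lab.reshape(
        s[0] // bs, bs, s[1] // bs, bs, s[2] // bs, bs
    ).transpose(0, 2, 4, 1, 3, 5)
    counts = [(blocks == l).sum(axis=(3, 4, 5)) for l in range(1, 5)]
    # lexicographic (count, label) maximum; label order equals priority order
    keys = np.stack([c * 8 + (l + 1) for l, c in zip(range(1, 5), counts)])
    best = np.argmax(keys, axis=0) + 1
    bone_count = sum(counts)
    return best.astype(np.uint8), bone_count


def _block_reduce_mean(vals: np.ndarray, mask: np.ndarray, bs: int) -> np.ndarray:
    """Per-block mean of vals over mask voxels (0 where mask empty)."""
    s = vals.shape
    vb = (vals * mask).reshape(
        s[0] // bs, bs, s[1] // bs, bs, s[2] // bs, bs
    ).transpose(0, 2, 4, 1, 3, 5).sum(axis=(3, 4, 5))
    nb = mask.reshape(
        s[0] // bs, bs, s[1] // bs, bs, s[2] // bs, bs
    ).transpose(0, 2, 4, 1, 3, 5).sum(axis=(3, 4, 5))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(nb > 0, vb / np.maximum(nb, 1), 0.0)
    return out


def _int_multiple(value: float, unit: float, what: str) -> int:
    m = int(round(value / unit))
    if m < 1 or abs(value - m * unit) > 1e-9 * max(1.0, value):
        raise InvalidInputError(
            f"{what} ({value} mm) must be a positive integer multiple of {unit} mm"
        )
    return m


def voxels_to_tets(
    labels: LabelVolume,
    image: VoxelImage,
    curve: CalibrationCurve = DEFAULT_CURVE,
    law: DensityModulusLaw = DEFAULT_LAW,
    fine_regions=(Label.SCL, Label.LYS),
    fine_edge_mm: float = 0.5,
    coarse_edge_mm: float = 1.0,
    fine_margin_mm: float = 2.0,
) -> TetrahedralMesh:
    """Build a two-resolution conforming tet mesh from a label volume.

    See the module docstring for the decomposition scheme.  Requires
    isotropic voxel spacing and commensurate cell edges.
    """
    lab = labels.labels
    if lab.shape != image.values.shape:
        raise InvalidInputError("label volume and image must be congruent")
    sp = np.asarray(image.spacing, dtype=float)
    if not np.allclose(sp, sp[0], rtol=0, atol=1e-9):
        raise InvalidInputError("voxels_to_tets requires isotropic voxel spacing")
    h = float(sp[0])
    if fine_edge_mm > coarse_edge_mm + 1e-12:
        raise InvalidInputError("fine_edge_mm must not exceed coarse_edge_mm")
    m = _int_multiple(fine_edge_mm, h, "fine_edge_mm")
    k = _int_multiple(coarse_edge_mm, fine_edge_mm, "coarse_edge_mm")
    cvox = m * k

    bone = lab != int(Label.OUTSIDE)
    if not bone.any():
        raise InvalidInputError("label volume contains no bone")

    rho_ash = rho_ct_to_rho_ash(hu_to_rho_ct(image.values, curve) / 1000.0, law)

    # pad to a whole number of coarse blocks
    shape = np.array(lab.shape)
    pshape = ((shape + cvox - 1) // cvox) * cvox
    pad = [(0, int(p - s)) for p, s in zip(pshape, shape)]
    lab_p = np.pad(lab, pad, constant_values=int(Label.OUTSIDE))
    bone_p = np.pad(bone, pad, constant_values=False)
    rho_p = np.pad(rho_ash, pad, constant_values=0.0)

    # coarse-block classification
    coarse_region, coarse_count = _block_reduce_labels(lab_p, cvox)
    coarse_rho = _block_reduce_mean(rho_p, bone_p, cvox)
    full = coarse_count == cvox**3
    some = coarse_count > 0

    fine_zone = np.zeros_like(full)
    lesion = np.isin(lab, [int(r) for r in fine_regions])
    if lesion.any():
        lo = np.maximum(np.min(np.argwhere(lesion), axis=0) - int(np.ceil(fine_margin_mm / h)), 0)
        hi = np.minimum(
            np.max(np.argwhere(lesion), axis=0) + int(np.ceil(fine_margin_mm / h)) + 1, pshape
        )
        blo, bhi = lo // cvox, (hi + cvox - 1) // cvox
        fine_zone[blo[0] : bhi[0], blo[1] : bhi[1], blo[2] : bhi[2]] = True

    refined = some & (~full | fine_zone)
    kuhn_cand = some & full & ~fine_zone
    fan = kuhn_cand & ndimage.binary_dilation(refined, structure=STRUCT_26)
    kuhn = kuhn_cand & ~fan

    # fine-cell (m-voxel) classification, over the whole padded grid
    fine_region, fine_count = _block_reduce_labels(lab_p, m)
    fine_rho = _block_reduce_mean(rho_p, bone_p, m)
    fine_full = fine_count == m**3

    book = _NodeBook()
    tets: list[tuple[int, int, int, int]] = []
    regions: list[int] = []
    rhos: list[float] = []

    def emit_kuhn(corner_lat, edge_lat, region, rho) -> None:
        for tpl in _KUHN:
            verts = corner_lat + tpl * edge_lat
            tets.append((book(verts[0]), book(verts[1]), book(verts[2]), book(verts[3])))
            regions.append(int(region))
            rhos.append(float(rho))

    E = 2 * k  # coarse edge in lattice units (lattice unit = fine_edge / 2)

    # refined blocks: included fine cells, Kuhn at fine edge (2 lattice units)
    for b in np.argwhere(refined):
        f0 = b * k
        for fi in range(k):
            for fj in range(k):
                for fk in range(k):
                    f = (f0[0] + fi, f0[1] + fj, f0[2] + fk)
                    if fine_full[f]:
                        emit_kuhn(np.array(f) * 2, 2, fine_region[f], fine_rho[f])

    # pure coarse blocks: Kuhn at coarse edge
    for b in np.argwhere(kuhn):
        emit_kuhn(b * E, E, coarse_region[tuple(b)], coarse_rho[tuple(b)])

    # transition (fan) blocks
    nb = np.array(refined.shape)

    def _is_refined(bidx) -> bool:
        if np.any(bidx < 0) or np.any(bidx >= nb):
            return False
        return bool(refined[tuple(bidx)])

    for b in np.argwhere(fan):
        base = b * E
        center = book(base + k)
        region = coarse_region[tuple(b)]
        rho = coarse_rho[tuple(b)]
        cpts = [book.coords[center]]
        for axis in range(3):
            u_ax, v_ax = [a for a in range(3) if a != axis]
            for side in (0, 1):

                def fpoint(u, v, _axis=axis, _side=side, _u=u_ax, _v=v_ax):
                    p = base.copy()
                    p[_axis] += _side * E
                    p[_u] += u
                    p[_v] += v
                    return p

                nbr = b.copy()
                nbr[axis] += 1 if side else -1
                face_tris: list[tuple] = []
                if _is_refined(nbr):
                    # fine-grid triangulation (matches fine Kuhn faces)
                    for iu in range(k):
                        for iv in range(k):
                            c = {
                                (du, dv): fpoint(2 * (iu + du), 2 * (iv + dv))
                                for du in (0, 1)
                                for dv in (0, 1)
                            }
                            for tri in _FACE_TRIS:
                                face_tris.append(tuple(book(c[t]) for t in tri))
                else:
                    # is any of the 4 face edges subdivided by a refined
                    # block elsewhere around that edge?
                    sub = []
                    d_ax = 1 if side else -1
                    for e_ax, e_side in ((v_ax, 0), (u_ax, 1), (v_ax, 1), (u_ax, 0)):
                        # edge runs along the remaining axis
                        d_e = 1 if e_side else -1
                        subdivided = False
                        for da in (0, d_ax):
                            for de in (0, d_e):
                                q = b.copy()
                                q[axis] += da
                                q[e_ax] += de
                                if (da or de) and _is_refined(q):
                                    subdivided = True
                        sub.append(subdivided)
                    if any(sub):
                        fc = book(fpoint(k, k))
                        loop: list[int] = []
                        corners = [(0, 0), (E, 0), (E, E), (0, E)]
                        for i_edge in range(4):
                            a = np.array(corners[i_edge])
                            bb = np.array(corners[(i_edge + 1) % 4])
                            nseg = k if sub[i_edge] else 1
                            for s in range(nseg):
                                pt = a + (bb - a) * s // nseg
                                loop.append(book(fpoint(pt[0], pt[1])))
                        for i in range(len(loop)):
                            face_tris.append((fc, loop[i], loop[(i + 1) % len(loop)]))
                    else:
                        c = {
                            (du, dv): book(fpoint(du * E, dv * E))
                            for du in (0, 1)
                            for dv in (0, 1)
                        }
                        for tri in _FACE_TRIS:
                            face_tris.append(tuple(c[t] for t in tri))
                for tri in face_tris:
                    tets.append((center, tri[0], tri[1], tri[2]))
                    regions.append(int(region))
                    rhos.append(float(rho))

    if not tets:
        raise InvalidInputError("no cells were meshed (bone too sparse for the cell size)")

    lattice = np.array(book.coords, dtype=np.int64)
    base_corner = np.asarray(image.origin, dtype=float) - h / 2.0
    nodes = base_corner + lattice * (fine_edge_mm / 2.0)
    tets_arr = np.array(tets, dtype=np.int64)

    # fix any negatively oriented tets (fan tets are emitted unordered)
    p = nodes[tets_arr]
    d = p[:, 1:] - p[:, :1]
    vol6 = np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2]))
    neg = vol6 < 0
    tets_arr[neg] = tets_arr[neg][:, [0, 2, 1, 3]]

    surface, owner = _boundary_facets(nodes, tets_arr)

    return TetrahedralMesh(
        nodes=nodes,
        tets=tets_arr,
        element_region=np.array(regions, dtype=np.uint8),
        element_rho_ash=np.array(rhos, dtype=float),
        surface_facets=surface,
        facet_owner=owner,
        fine_edge_mm=float(fine_edge_mm),
        coarse_edge_mm=float(coarse_edge_mm),
    )


def _boundary_facets(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundary triangles (outward oriented) and their owner tets."""
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)
    owners = np.repeat(np.arange(tets.shape[0]), 4)
    opposite = tets[:, [0, 1, 2, 3]].reshape(-1)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    sel = counts[inv] == 1
    bfaces = faces[sel]
    bown = owners[sel]
    bopp = opposite[sel]
    # orient outward: normal must point away from the opposite vertex
    a, b, c = nodes[bfaces[:, 0]], nodes[bfaces[:, 1]], nodes[bfaces[:, 2]]
    n = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", n, a - nodes[bopp]) < 0
    bfaces[inward] = bfaces[inward][:, [0, 2, 1]]
    return bfaces, bown


def tag_boundary_sets(
    mesh: TetrahedralMesh,
    frame: AnatomicalFrame,
    psg_plane: PsgStripSpec,
    load_patch_spec: LoadPatchSpec,
    strip_width_mm: float = 3.0,
    proximal_band_mm: float | None = None,
) -> TetrahedralMesh:
    """Tag PROXIMAL_FIXED nodes and PSG_STRIP / LOAD_SURFACE facets.

    PROXIMAL_FIXED: boundary nodes within one coarse edge (or
    ``proximal_band_mm``) of the proximal cut plane.  PSG_STRIP: boundary
    facets whose centroid is within half the strip width of the groove
    plane (restricted axially per the spec).  LOAD_SURFACE: boundary facets
    selected by the load-patch spec, excluding the proximal band.
    Mutates and returns ``mesh``.
    """
    if strip_width_mm <= 0:
        raise DegenerateGeometryError("strip_width_mm must be positive")
    if mesh.surface_facets.shape[0] == 0:
        raise DegenerateGeometryError("mesh has no boundary")
    band = mesh.coarse_edge_mm if proximal_band_mm is None else float(proximal_band_mm)

    t_nodes = frame.axial_coordinate(mesh.nodes)
    boundary_nodes = np.unique(mesh.surface_facets)
    t_max = t_nodes[boundary_nodes].max()
    t_min = t_nodes[boundary_nodes].min()
    proximal = boundary_nodes[t_nodes[boundary_nodes] >= t_max - band - 1e-9]

    centroids = mesh.facet_centroids()
    normals, _ = mesh.facet_normals_areas()
    t_cent = frame.axial_coordinate(centroids)
    non_proximal = t_cent < t_max - band - 1e-9

    n_plane = psg_plane.unit_normal()
    dist = np.abs((centroids - np.asarray(psg_plane.point_mm)) @ n_plane)
    strip = dist <= strip_width_mm / 2.0
    if psg_plane.max_distal_distance_mm is not None:
        strip &= (t_cent - t_min) <= psg_plane.max_distal_distance_mm
    strip &= non_proximal
    strip_idx = np.flatnonzero(strip)

    if load_patch_spec.whole_boundary:
        load_idx = np.flatnonzero(non_proximal)
    else:
        if load_patch_spec.center_mm is None or load_patch_spec.radius_mm is None:
            raise InvalidInputError("load patch spec needs center_mm and radius_mm")
        in_patch = (
            np.linalg.norm(centroids - np.asarray(load_patch_spec.center_mm), axis=1)
            <= load_patch_spec.radius_mm
        )
        if load_patch_spec.direction is not None:
            d = np.asarray(load_patch_spec.direction, dtype=float)
            d = d / np.linalg.norm(d)
            in_patch &= normals @ d >= load_patch_spec.min_normal_dot
        load_idx = np.flatnonzero(in_patch & non_proximal)

    for name, arr in (
        ("PROXIMAL_FIXED", proximal),
        ("PSG_STRIP", strip_idx),
        ("LOAD_SURFACE", load_idx),
    ):
        if arr.size == 0:
            raise DegenerateGeometryError(f"boundary set {name} is empty")

    mesh.node_sets["PROXIMAL_FIXED"] = proximal
    mesh.facet_sets["PSG_STRIP"] = strip_idx
    mesh.facet_sets["LOAD_SURFACE"] = load_idx
    mesh.node_sets["PSG_STRIP"] = np.unique(mesh.surface_facets[strip_idx])
    mesh.node_sets["LOAD_SURFACE"] = np.unique(mesh.surface_facets[load_idx])
    return mesh
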