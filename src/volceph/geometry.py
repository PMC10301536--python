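"""Landmark-free 3D geometry: planes, watertight plane cuts, mesh volumes.

All coordinates are in millimetres and all volumes in mm³ (STL carries no
units; mm is asserted by convention throughout the package).  Meshes are
`trimesh.Trimesh` objects that must be watertight (every edge shared by
exactly two faces), consistently wound and outward-oriented (signed volume
positive).  Face/vertex indexing is 0-based.

The two volume routes are deliberately independent: :func:`mesh_volume` sums
signed tetrahedra (divergence theorem), while :func:`voxel_volume_oracle`
counts voxel centres inside the surface by ray-parity -- the latter exists to
cross-check the former in tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import (
    DegeneratePlaneError,
    MeshIntegrityError,
    OrientationError,
    VoxelBudgetError,
)
from .triangulate import triangulate_loops

log = logging.getLogger(__name__)

__all__ = [
    "Plane",
    "PLANE_SNAP_MM",
    "plane_from_points",
    "plane_fit",
    "signed_distance",
    "mesh_volume",
    "cut_mesh",
    "voxel_volume_oracle",
    "boundary_edge_count",
    "require_watertight",
    "ensure_outward",
]

#: snap-to-plane tolerance for vertex classification during cutting (mm)
PLANE_SNAP_MM = 1e-9


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane ``{p : normal . p = offset}``.

    ``normal`` is a unit 3-vector; ``offset`` is in mm.  The orientation
    (which side is "positive") is semantically meaningful: anatomical planes
    are oriented superior or anterior by convention.
    """

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,) or not np.all(np.isfinite(n)):
            raise DegeneratePlaneError(f"invalid plane normal {n!r}")
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            if norm < 1e-12:
                raise DegeneratePlaneError("zero-length plane normal")
            n = n / norm
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))
        self.normal.setflags(write=False)

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance in mm; positive on the side the normal points to."""
        p = np.asarray(points, dtype=float)
        d = p @ self.normal - self.offset
        return float(d) if p.ndim == 1 else d

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane basis (u, v) with u x v = normal."""
        n = self.normal
        a = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def origin(self) -> np.ndarray:
        return self.normal * self.offset


def signed_distance(plane: Plane, point) -> float:
    """Functional form of :meth:`Plane.signed_distance`."""
    return plane.signed_distance(point)


def plane_from_points(p1, p2, p3, orient_toward=None) -> Plane:
    """Exact plane through three non-collinear points.

    If ``orient_toward`` is given, the normal is flipped (if needed) so that
    point has non-negative signed distance.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    # |n| = 2 * triangle area
    if np.linalg.norm(n) <= 2e-9:
        raise DegeneratePlaneError(
            f"collinear points cannot define a plane: {p1.tolist()}, "
            f"{p2.tolist()}, {p3.tolist()}"
        )
    n = n / np.linalg.norm(n)
    plane = Plane(n, float(n @ p1))
    if orient_toward is not None and plane.signed_distance(orient_toward) < 0:
        plane = plane.flipped()
    return plane


def plane_fit(points, orient_toward=None) -> Plane:
    """Least-squares plane minimising squared orthogonal distances (SVD).

    Reduces to :func:`plane_from_points` for exactly three points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegeneratePlaneError("plane_fit needs >= 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] <= 1e-9 * max(s[0], 1.0):  # rank < 2: collinear configuration
        raise DegeneratePlaneError("points are collinear; plane fit is rank-deficient")
    n = vt[2]
    plane = Plane(n, float(n @ centroid))
    if orient_toward is not None and plane.signed_distance(orient_toward) < 0:
        plane = plane.flipped()
    return plane


# ---------------------------------------------------------------------------
# mesh integrity helpers
# ---------------------------------------------------------------------------

def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges referenced by exactly one face."""
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


def require_watertight(mesh: trimesh.Trimesh, what: str = "mesh") -> None:
    """Raise :class:`MeshIntegrityError` unless watertight and outward."""
    if mesh is None or len(mesh.faces) == 0:
        raise MeshIntegrityError(f"{what} is empty")
    if not mesh.is_watertight:
        raise MeshIntegrityError(
            f"{what} is not watertight", boundary_edges=boundary_edge_count(mesh)
        )
    if not mesh.is_winding_consistent:
        raise OrientationError(f"{what} has inconsistent face winding")
    if _signed_volume(mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray)) < 0:
        raise OrientationError(
            f"{what} is inward-oriented (negative signed volume); "
            "flip its faces (see ensure_outward)"
        )


def ensure_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Flip all faces if the signed volume is negative (warns; STL exporters
    disagree on winding)."""
    v = _signed_volume(mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray))
    if v < 0:
        warnings.warn("mesh was inward-oriented; flipping all faces", stacklevel=2)
        mesh = trimesh.Trimesh(
            vertices=mesh.vertices.copy(), faces=mesh.faces[:, ::-1].copy(),
            process=False,
        )
    return mesh


def _signed_volume(V: np.ndarray, F: np.ndarray) -> float:
    if len(F) == 0:
        return 0.0
    a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Volume (mm³) by the signed-tetrahedron sum V = (1/6) Σ det[a, b, c].

    The mesh must be watertight and outward-oriented; a negative signed sum
    raises :class:`OrientationError` rather than being silently absoluted.
    """
    require_watertight(mesh)
    return _signed_volume(mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray))


# ---------------------------------------------------------------------------
# plane cutting with capping
# ---------------------------------------------------------------------------

def _chain_loops(boundary_edges: list[tuple[int, int]]) -> list[list[int]]:
    """Chain directed boundary edges into closed loops."""
    succ: dict[int, int] = {}
    for i, j in boundary_edges:
        if i in succ:
            raise MeshIntegrityError(
                "non-manifold cut boundary (vertex with two outgoing edges)"
            )
        succ[i] = j
    loops = []
    remaining = dict(succ)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        cur = remaining.pop(start)
        while cur != start:
            loop.append(cur)
            nxt = remaining.pop(cur, None)
            if nxt is None:
                raise MeshIntegrityError("open cut boundary chain")
            cur = nxt
        loops.append(loop)
    return loops


def _cap(faces: list[list[int]], W: np.ndarray, plane: Plane, inward_normal_sign: float):
    """Append cap triangles closing the open boundary of ``faces``.

    ``inward_normal_sign`` = -1 caps the piece kept *above* the plane (cap
    outward normal is -plane.normal), +1 the piece below.
    """
    F = np.asarray(faces, dtype=np.int64)
    edges = F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    es = np.sort(edges, axis=1)
    _, inv, counts = np.unique(es, axis=0, return_inverse=True, return_counts=True)
    open_mask = counts[inv] == 1
    boundary = [tuple(e) for e in edges[open_mask]]
    if not boundary:
        return faces
    loops = _chain_loops(boundary)
    u, v = plane.basis()
    loops_2d = [np.column_stack([W[lp] @ u, W[lp] @ v]) for lp in loops]
    tris = triangulate_loops(loops_2d, loops)
    want = inward_normal_sign * plane.normal
    capped = list(faces)
    for (i, j, k) in tris:
        n = np.cross(W[j] - W[i], W[k] - W[i])
        if n @ want < 0:
            i, j, k = i, k, j
        capped.append([i, j, k])
    return capped


def _finalize_piece(faces: list[list[int]], W: np.ndarray) -> trimesh.Trimesh | None:
    if not faces:
        return None
    F = np.asarray(faces, dtype=np.int64)
    used = np.unique(F)
    remap = np.full(len(W), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    piece = trimesh.Trimesh(vertices=W[used], faces=remap[F], process=False)
    # drop exact-duplicate-vertex (zero area) faces if any slipped through
    fv = piece.faces
    degen = (fv[:, 0] == fv[:, 1]) | (fv[:, 1] == fv[:, 2]) | (fv[:, 0] == fv[:, 2])
    if degen.any():
        piece = trimesh.Trimesh(
            vertices=piece.vertices, faces=fv[~degen], process=False
        )
    return piece if len(piece.faces) else None


def cut_mesh(
    mesh: trimesh.Trimesh, plane: Plane, snap_mm: float = PLANE_SNAP_MM
) -> tuple[trimesh.Trimesh | None, trimesh.Trimesh | None]:
    """Split a watertight mesh by a plane into (above, below) watertight pieces.

    Cross-sections are capped with triangulated planar polygons (multiple
    loops and loops with holes are supported).  Vertices within ``snap_mm`` of
    the plane are snapped onto it before splitting, avoiding sliver triangles;
    intersection vertices are cached per edge so both pieces share identical
    cut vertices and volumes add up to the input volume to machine precision.

    Returns ``None`` for a side the plane does not reach.
    """
    require_watertight(mesh)
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=np.int64)
    d = V @ plane.normal - plane.offset
    # effective snap scales with the mesh extent: vertices grazing the plane
    # by float round-off would otherwise spawn coincident intersection points
    # and sliver caps
    extent = float(np.ptp(V, axis=0).max()) or 1.0
    snap = max(snap_mm, 1e-8 * extent)
    d = np.where(np.abs(d) <= snap, 0.0, d)

    if np.all(d >= 0):
        return (trimesh.Trimesh(vertices=V.copy(), faces=F.copy(), process=False), None)
    if np.all(d <= 0):
        return (None, trimesh.Trimesh(vertices=V.copy(), faces=F.copy(), process=False))

    new_verts: list[np.ndarray] = []
    edge_cache: dict[tuple[int, int], int] = {}
    nV = len(V)

    def edge_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = edge_cache.get(key)
        if idx is None:
            a, b = key
            t = d[a] / (d[a] - d[b])
            p = V[a] + t * (V[b] - V[a])
            idx = nV + len(new_verts)
            new_verts.append(p)
            edge_cache[key] = idx
        return idx

    above: list[list[int]] = []
    below: list[list[int]] = []
    sgn = np.sign(d)
    fs = sgn[F]
    fmin = fs.min(axis=1)
    fmax = fs.max(axis=1)
    face_normals = None
    for fi in range(len(F)):
        lo, hi = fmin[fi], fmax[fi]
        tri = F[fi]
        if lo >= 0 and hi > 0:
            above.append(list(tri))
        elif hi <= 0 and lo < 0:
            below.append(list(tri))
        elif lo == 0 and hi == 0:
            # face fully coplanar with the cut: it bounds the solid on the
            # side opposite its outward normal
            if face_normals is None:
                face_normals = np.cross(
                    V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]]
                )
            if face_normals[fi] @ plane.normal < 0:
                above.append(list(tri))
            else:
                below.append(list(tri))
        else:
            # straddling face: clip into per-side polygons (Sutherland-Hodgman)
            for keep, out in ((1.0, above), (-1.0, below)):
                poly: list[int] = []
                for k in range(3):
                    i, j = int(tri[k]), int(tri[(k + 1) % 3])
                    if d[i] * keep >= 0:
                        poly.append(i)
                    if (d[i] > 0 and d[j] < 0) or (d[i] < 0 and d[j] > 0):
                        poly.append(edge_point(i, j))
                if len(poly) >= 3:
                    for k in range(1, len(poly) - 1):
                        tri_k = [poly[0], poly[k], poly[k + 1]]
                        if len(set(tri_k)) == 3:
                            out.append(tri_k)

    W = np.vstack([V] + new_verts) if new_verts else V
    above = _cap(above, W, plane, -1.0) if above else above
    below = _cap(below, W, plane, +1.0) if below else below
    pa = _finalize_piece(above, W)
    pb = _finalize_piece(below, W)
    for piece, name in ((pa, "above"), (pb, "below")):
        if piece is not None:
            require_watertight(piece, what=f"cut result ({name} side)")
    return pa, pb


# ---------------------------------------------------------------------------
# voxel parity oracle
# ---------------------------------------------------------------------------

def voxel_volume_oracle(
    mesh: trimesh.Trimesh,
    voxel_mm: float,
    max_cells: int = 100_000_000,
) -> float:
    """Volume estimate: count of voxel centres inside the surface x voxel³.

    Inside/outside is decided by the parity of surface crossings along the
    vertical (z) ray through each centre -- a route entirely independent of
    the signed-tetrahedron formula.  The grid is given a tiny deterministic
    jitter so centres do not fall exactly on edges; if a column still shows an
    odd crossing count the grid is re-jittered (up to 4 attempts).

    Error bound: |estimate - true volume| = O(surface area x voxel_mm).
    """
    require_watertight(mesh)
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be > 0")
    lo, hi = mesh.bounds
    h = float(voxel_mm)
    dims = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 1)
    if int(np.prod(dims.astype(np.int64))) > max_cells:
        raise VoxelBudgetError(
            f"grid {tuple(dims)} exceeds budget of {max_cells} cells; "
            "use a larger voxel_mm"
        )
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=np.int64)
    T = V[F]  # (m, 3, 3)
    scale = float(np.max(hi - lo)) or 1.0

    for attempt in range(4):
        jit = h * 1e-4 * (1 + attempt) * np.array([0.7548776, 0.56984029, 0.36602540])
        org = lo + h / 2.0 + jit
        nx, ny = int(dims[0]), int(dims[1])
        cols: list[np.ndarray] = []
        zs: list[np.ndarray] = []
        for t in T:
            (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
            det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
            if abs(det) < 1e-14 * scale * scale:
                continue  # vertical triangle: zero-measure projection
            xmin, xmax = min(x0, x1, x2), max(x0, x1, x2)
            ymin, ymax = min(y0, y1, y2), max(y0, y1, y2)
            ix0 = max(int(np.ceil((xmin - org[0]) / h)), 0)
            ix1 = min(int(np.floor((xmax - org[0]) / h)), nx - 1)
            iy0 = max(int(np.ceil((ymin - org[1]) / h)), 0)
            iy1 = min(int(np.floor((ymax - org[1]) / h)), ny - 1)
            if ix1 < ix0 or iy1 < iy0:
                continue
            gx = org[0] + h * np.arange(ix0, ix1 + 1)
            gy = org[1] + h * np.arange(iy0, iy1 + 1)
            PX, PY = np.meshgrid(gx, gy, indexing="ij")
            w1 = ((PX - x0) * (y2 - y0) - (x2 - x0) * (PY - y0)) / det
            w2 = ((x1 - x0) * (PY - y0) - (PX - x0) * (y1 - y0)) / det
            w0 = 1.0 - w1 - w2
            inside = (w0 > 0) & (w1 > 0) & (w2 > 0)
            if not inside.any():
                continue
            zc = w0 * z0 + w1 * z1 + w2 * z2
            II, JJ = np.meshgrid(
                np.arange(ix0, ix1 + 1), np.arange(iy0, iy1 + 1), indexing="ij"
            )
            cols.append((II[inside] * ny + JJ[inside]).ravel())
            zs.append(zc[inside].ravel())
        if not cols:
            return 0.0
        col = np.concatenate(cols)
        z = np.concatenate(zs)
        counts = np.bincount(col)
        if np.any(counts % 2 == 1):
            log.debug("voxel oracle: odd crossing parity, re-jittering grid")
            continue
        order = np.lexsort((z, col))
        z_sorted = z[order]
        z_lo = z_sorted[0::2]
        z_hi = z_sorted[1::2]
        # centres org_z + m*h with z in (z_lo, z_hi]
        m_hi = np.floor((z_hi - org[2]) / h)
        m_lo = np.floor((z_lo - org[2]) / h)
        n_inside = int(np.sum(np.maximum(m_hi - m_lo, 0)))
        return n_inside * h**3
    raise MeshIntegrityError(
        "voxel oracle could not obtain even ray-crossing parity; "
        "mesh may be degenerate"
    )
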