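"""Planar polygon triangulation used to cap mesh cross-sections.

Cutting a watertight surface with a plane leaves one or more closed boundary
loops in that plane.  The loops may be nested (a loop inside a loop is a hole,
by the even-odd rule).  This module triangulates such a loop family in 2D:
holes are spliced into their enclosing shell with bridge edges (shortest
mutually visible vertex pair) and the resulting simple polygon is ear-clipped.

Only loop vertices are used -- no Steiner points -- so cap triangles reference
existing mesh vertices and the capped mesh stays watertight by construction.
Collinear loop vertices (cut points along a straight mesh edge) are removed
before ear clipping and restored afterwards by splitting the cap triangle
edges they lie on, which keeps edge topology exact without emitting
zero-area triangles.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .errors import TriangulationError

__all__ = ["triangulate_loops"]


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _simplify_collinear(ring_xy: np.ndarray, ring_idx: list[int], area_eps: float):
    """Drop vertices whose corner is (near-)collinear; record them per edge.

    Returns (xy, idx, interior) where ``interior`` maps a directed simplified
    edge ``(a, b)`` to the ordered mesh-vertex indices lying on it.
    """
    xy = [p for p in ring_xy]
    idx = list(ring_idx)
    removed: list[tuple[int, np.ndarray]] = []  # (mesh idx, position)
    changed = True
    while changed and len(idx) > 3:
        changed = False
        m = len(idx)
        for k in range(m):
            a, b, c = xy[(k - 1) % m], xy[k], xy[(k + 1) % m]
            if abs(_cross(a, b, c)) <= area_eps:
                removed.append((idx[k], xy[k]))
                xy.pop(k)
                idx.pop(k)
                changed = True
                break
    interior: dict[tuple[int, int], list[int]] = {}
    if removed:
        xy_arr = np.asarray(xy)
        m = len(idx)
        for vi, p in removed:
            # find the simplified edge this point lies on
            best, best_d = None, np.inf
            for k in range(m):
                a, b = xy_arr[k], xy_arr[(k + 1) % m]
                ab = b - a
                L2 = float(ab @ ab)
                if L2 == 0.0:
                    continue
                t = float((p - a) @ ab) / L2
                if t < -1e-9 or t > 1 + 1e-9:
                    continue
                d = float(np.linalg.norm(a + t * ab - p))
                if d < best_d:
                    best, best_d = (idx[k], idx[(k + 1) % m], t), d
            if best is None:
                raise TriangulationError("lost a collinear cap vertex")
            a_i, b_i, t = best
            interior.setdefault((a_i, b_i), []).append((t, vi))
        interior = {
            e: [vi for _, vi in sorted(lst)] for e, lst in interior.items()
        }
    return np.asarray(xy), idx, interior


def _blocks(tri_xy: np.ndarray, others: np.ndarray, eps: float, corner_tol: float) -> bool:
    """Does any point in ``others`` lie inside or on the CCW triangle
    (points coincident with a triangle corner do not block)?"""
    if len(others) == 0:
        return False
    a, b, c = tri_xy
    d1 = (b[0] - a[0]) * (others[:, 1] - a[1]) - (b[1] - a[1]) * (others[:, 0] - a[0])
    d2 = (c[0] - b[0]) * (others[:, 1] - b[1]) - (c[1] - b[1]) * (others[:, 0] - b[0])
    d3 = (a[0] - c[0]) * (others[:, 1] - c[1]) - (a[1] - c[1]) * (others[:, 0] - c[0])
    on_or_in = (d1 >= -eps) & (d2 >= -eps) & (d3 >= -eps)
    if not on_or_in.any():
        return False
    pts = others[on_or_in]
    for corner in (a, b, c):
        on_or_in_pts = np.linalg.norm(pts - corner, axis=1) <= corner_tol
        pts = pts[~on_or_in_pts]
    return len(pts) > 0


def _ear_clip(ring_xy: np.ndarray, ring_idx: list[int]) -> list[tuple[int, int, int]]:
    """Triangulate a simple CCW polygon (no collinear corners) by ear clipping."""
    n = len(ring_idx)
    if n < 3:
        return []
    scale = float(np.ptp(ring_xy, axis=0).max()) or 1.0
    area_eps = 1e-12 * scale * scale
    corner_tol = 1e-9 * scale
    pos = list(range(n))
    tris: list[tuple[int, int, int]] = []
    while len(pos) > 3:
        m = len(pos)
        clipped = False
        for k in range(m):
            ip, ic, inx = pos[(k - 1) % m], pos[k], pos[(k + 1) % m]
            a, b, c = ring_xy[ip], ring_xy[ic], ring_xy[inx]
            if _cross(a, b, c) <= area_eps:  # reflex or degenerate corner
                continue
            others = np.array([ring_xy[p] for p in pos if p not in (ip, ic, inx)])
            if _blocks(np.array([a, b, c]), others, area_eps, corner_tol):
                continue
            tris.append((ring_idx[ip], ring_idx[ic], ring_idx[inx]))
            pos.pop(k)
            clipped = True
            break
        if not clipped:
            raise TriangulationError("no ear found (self-intersecting cap loop?)")
    ip, ic, inx = pos
    if abs(_cross(ring_xy[ip], ring_xy[ic], ring_xy[inx])) > area_eps:
        tris.append((ring_idx[ip], ring_idx[ic], ring_idx[inx]))
    else:
        raise TriangulationError("degenerate final ear")
    return tris


def _bridge(shell_xy, shell_idx, hole_xy, hole_idx, region: Polygon):
    """Splice a hole ring into the shell via the shortest interior bridge."""
    best = None
    for hi in range(len(hole_xy)):
        d2 = np.sum((np.asarray(shell_xy) - hole_xy[hi]) ** 2, axis=1)
        for si in np.argsort(d2):
            seg = LineString([hole_xy[hi], shell_xy[si]])
            if seg.length == 0.0:
                continue
            if region.buffer(1e-9).covers(seg):
                best = (int(si), int(hi))
                break
        if best is not None:
            break
    if best is None:
        raise TriangulationError("could not bridge a cap hole to its shell")
    si, hi = best
    new_xy = np.vstack(
        [shell_xy[: si + 1], hole_xy[hi:], hole_xy[: hi + 1], shell_xy[si:]]
    )
    new_idx = (
        shell_idx[: si + 1] + hole_idx[hi:] + hole_idx[: hi + 1] + shell_idx[si:]
    )
    return new_xy, new_idx


def _subdivide_edges(
    tris: list[tuple[int, int, int]],
    interior: dict[tuple[int, int], list[int]],
) -> list[tuple[int, int, int]]:
    """Split cap triangle edges to restore removed collinear vertices."""
    if not interior:
        return tris
    lookup: dict[tuple[int, int], list[int]] = {}
    for (a, b), vs in interior.items():
        lookup[(a, b)] = vs
        lookup[(b, a)] = vs[::-1]
    out: list[tuple[int, int, int]] = []
    stack = list(tris)
    while stack:
        i, j, k = stack.pop()
        done = True
        for (a, b, apex) in ((i, j, k), (j, k, i), (k, i, j)):
            vs = lookup.get((a, b))
            if vs:
                chain = [a] + vs + [b]
                for t in range(len(chain) - 1):
                    stack.append((chain[t], chain[t + 1], apex))
                # consume so nested subdivision doesn't loop forever
                del lookup[(a, b)]
                lookup.pop((b, a), None)
                done = False
                break
        if done:
            out.append((i, j, k))
    return out


def triangulate_loops(loops: list[np.ndarray], indices: list[list[int]]):
    """Triangulate a family of closed 2D loops under the even-odd rule.

    Parameters
    ----------
    loops : list of (n_i, 2) float arrays
        Closed loops (last vertex implicitly connects to the first).
    indices : list of lists of int
        For each loop vertex, the caller's (3D mesh) vertex index; triangles
        are emitted in terms of these indices.

    Returns
    -------
    list of (i, j, k) triangles covering the even-odd interior.  Winding is
    arbitrary per triangle; callers orient caps by the plane normal.
    """
    if len(loops) != len(indices):
        raise ValueError("loops and indices length mismatch")
    scale = max(
        (float(np.ptp(lp, axis=0).max()) for lp in loops if len(lp)), default=1.0
    ) or 1.0
    area_eps = 1e-10 * scale * scale

    simplified = []
    for lp, idx in zip(loops, indices):
        if len(lp) < 3 or abs(_signed_area(np.asarray(lp, float))) <= area_eps:
            continue  # zero-area loop contributes nothing
        xy, sidx, interior = _simplify_collinear(
            np.asarray(lp, float), list(idx), area_eps
        )
        if len(sidx) >= 3:
            simplified.append((xy, sidx, interior))
    if not simplified:
        return []

    polys = [Polygon(xy) for xy, _, _ in simplified]
    # nesting depth uses a point ON each ring (a filled polygon's interior
    # representative point could fall inside a nested hole)
    reps = [Point(xy[0]) for xy, _, _ in simplified]
    depth = [
        sum(1 for j, q in enumerate(polys) if j != i and q.contains(reps[i]))
        for i in range(len(polys))
    ]
    shells = [i for i in range(len(polys)) if depth[i] % 2 == 0]
    holes = [i for i in range(len(polys)) if depth[i] % 2 == 1]
    hole_of: dict[int, list[int]] = {s: [] for s in shells}
    for h in holes:
        cands = [s for s in shells if polys[s].contains(reps[h])]
        if not cands:
            raise TriangulationError("cap hole loop has no enclosing shell")
        hole_of[min(cands, key=lambda s: polys[s].area)].append(h)

    tris: list[tuple[int, int, int]] = []
    all_interior: dict[tuple[int, int], list[int]] = {}
    for _, _, interior in simplified:
        all_interior.update(interior)

    for s in shells:
        shell_xy, shell_idx, _ = simplified[s]
        if _signed_area(shell_xy) < 0:  # shells CCW
            shell_xy = shell_xy[::-1]
            shell_idx = shell_idx[::-1]
        hole_rings = []
        for h in hole_of[s]:
            hx, hidx, _ = simplified[h]
            if _signed_area(hx) > 0:  # holes CW
                hx, hidx = hx[::-1], hidx[::-1]
            hole_rings.append((hx, hidx))
        if hole_rings:
            region = Polygon(shell_xy, [hx for hx, _ in hole_rings])
            hole_rings.sort(key=lambda t: -t[0][:, 0].max())
            for hx, hidx in hole_rings:
                shell_xy, shell_idx = _bridge(shell_xy, shell_idx, hx, hidx, region)
        tris.extend(_ear_clip(np.asarray(shell_xy), list(shell_idx)))

    return _subdivide_edges(tris, all_interior)
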