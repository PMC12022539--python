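"""Independent brute-force oracles for the pattern statistics.

These deliberately avoid scipy.spatial: the hull is found by gift wrapping,
Delaunay edges by enumerating all triangles and testing circumcircles for
emptiness, and the distance statistics by full pairwise scans.  They are
O(n^4)-ish and only meant for instances of <= ~60 points.
"""

from __future__ import annotations

import itertools

import numpy as np


def convex_hull_indices(points: np.ndarray) -> set[int]:
    """Strict hull vertex indices via Andrew's monotone chain.

    Collinear points on a hull edge are excluded (they are handled by the
    edge-line tolerance in :func:`brute_boundary`).
    """
    pts = np.asarray(points, dtype=float)
    order = list(np.lexsort((pts[:, 1], pts[:, 0])))

    def chain(indices):
        out: list[int] = []
        for i in indices:
            while len(out) >= 2:
                o, a = pts[out[-2]], pts[out[-1]]
                cross = (a[0] - o[0]) * (pts[i][1] - o[1]) - (a[1] - o[1]) * (
                    pts[i][0] - o[0]
                )
                if cross <= 0:  # right turn or collinear: drop
                    out.pop()
                else:
                    break
            out.append(i)
        return out

    lower = chain(order)
    upper = chain(order[::-1])
    return set(lower[:-1] + upper[:-1])


def _circumcircle(a, b, c):
    """Center and squared radius of the circle through three points."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14 * max(1.0, abs(ax) + abs(bx) + abs(cx)) ** 2:
        return None
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def brute_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edges by empty-circumcircle enumeration of all triangles."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        cc = _circumcircle(pts[i], pts[j], pts[k])
        if cc is None:
            continue
        (ux, uy), r2 = cc
        d2 = (pts[:, 0] - ux) ** 2 + (pts[:, 1] - uy) ** 2
        inside = d2 < r2 * (1.0 - 1e-12)
        inside[[i, j, k]] = False
        if not inside.any():
            edges.update({(i, j), (i, k), (j, k)})
    return {(min(a, b), max(a, b)) for a, b in edges}


def brute_boundary(points: np.ndarray, tol_rel: float = 1e-9) -> set[int]:
    """Indices on the hull outline: hull vertices (gift wrapping) plus any
    point within ``tol_rel x extent`` of a hull edge line."""
    pts = np.asarray(points, dtype=float)
    hull = sorted(convex_hull_indices(pts))
    ordered = _order_hull(pts, set(hull))
    extent = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    tol = tol_rel * extent
    boundary = set(hull)
    for k in range(len(ordered)):
        a = pts[ordered[k]]
        b = pts[ordered[(k + 1) % len(ordered)]]
        edge = b - a
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        for i in range(len(pts)):
            if abs((pts[i] - a) @ normal) <= tol:
                boundary.add(i)
    return boundary


def _order_hull(pts: np.ndarray, hull: set[int]) -> list[int]:
    """Hull vertex indices in angular order around their centroid."""
    idx = sorted(hull)
    center = pts[idx].mean(axis=0)
    return sorted(idx, key=lambda i: np.arctan2(*(pts[i] - center)[::-1]))


def brute_hexagonality(points: np.ndarray, jittered: np.ndarray | None = None) -> float:
    """Fraction of interior points with Delaunay degree 6, by brute force.

    The interior/boundary split comes from ``points``; the triangulation is
    built on ``jittered`` when given (for degenerate inputs), mirroring the
    documented tie-break convention.
    """
    pts = np.asarray(points, dtype=float)
    work = pts if jittered is None else np.asarray(jittered, dtype=float)
    degree = np.zeros(len(pts), dtype=int)
    for i, j in brute_delaunay_edges(work):
        degree[i] += 1
        degree[j] += 1
    boundary = brute_boundary(pts)
    interior = [i for i in range(len(pts)) if i not in boundary]
    if not interior:
        raise ValueError("no interior points")
    return float(np.mean(degree[interior] == 6))


def brute_nn_cv(points: np.ndarray) -> float:
    """Nearest-neighbor distance CV via a full pairwise-distance scan."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    nn = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = float(np.hypot(*(pts[i] - pts[j])))
                nn[i] = min(nn[i], d)
    return float(np.std(nn) / np.mean(nn))


def brute_symmetry_error(
    points: np.ndarray, axis_angle_deg: float, axis_point=(0.0, 0.0)
) -> float:
    """Direct recomputation of the mirror-symmetry score definition."""
    pts = np.asarray(points, dtype=float)
    t = np.deg2rad(axis_angle_deg)
    u = np.array([np.cos(t), np.sin(t)])
    p0 = np.asarray(axis_point, dtype=float)
    total = 0.0
    for p in pts:
        rel = p - p0
        mirrored = 2.0 * (rel @ u) * u - rel + p0
        total += min(np.hypot(*(mirrored - q)) for q in pts)
    mean_mirror = total / len(pts)
    if mean_mirror == 0.0:
        return 0.0
    nn = []
    for i, p in enumerate(pts):
        nn.append(min(np.hypot(*(p - q)) for j, q in enumerate(pts) if j != i))
    return mean_mirror / float(np.mean(nn))
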