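"""Computational-geometry primitives for shape measurement.

These are the two non-trivial primitives behind the descriptor set: the
maximum caliper diameter (Feret) via rotating calipers on the convex hull,
and the minimal enclosing circle via Welzl's move-to-front algorithm (with
a fixed-seed permutation, so results are reproducible bit for bit).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-10


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float((a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0]))


def rotating_calipers_diameter(hull: np.ndarray) -> tuple[float, int, int]:
    """Maximum pairwise distance over the vertices of a convex polygon.

    Parameters
    ----------
    hull : (m, 2) ndarray
        Convex polygon vertices in counter-clockwise order, no duplicates.

    Returns
    -------
    diameter, i, j
        The diameter and the indices of a realising antipodal pair.
    """
    pts = np.asarray(hull, dtype=float)
    m = len(pts)
    if m == 1:
        return 0.0, 0, 0
    if m == 2:
        return float(np.linalg.norm(pts[1] - pts[0])), 0, 1

    def area2(i: int, j: int, k: int) -> float:
        return _cross(pts[i], pts[j], pts[k])

    best = -1.0
    bi = bj = 0
    j = 1
    for i in range(m):
        ni = (i + 1) % m
        # advance the caliper while the triangle on edge (i, ni) grows
        while True:
            nj = (j + 1) % m
            if area2(i, ni, nj) > area2(i, ni, j) + _EPS * (
                abs(area2(i, ni, j)) + 1.0
            ):
                j = nj
            else:
                break
        for k in (j, (j + 1) % m):
            d = float(np.linalg.norm(pts[k] - pts[i]))
            if d > best:
                best, bi, bj = d, i, k
            d = float(np.linalg.norm(pts[k] - pts[ni]))
            if d > best:
                best, bi, bj = d, ni, k
    return best, bi, bj


def _circle_from_two(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    centre = (a + b) / 2.0
    return centre, float(np.linalg.norm(a - b)) / 2.0


def _circle_from_three(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, float] | None:
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < _EPS * (abs(ax) + abs(ay) + abs(bx) + abs(by) + abs(cx) + abs(cy) + 1.0):
        return None  # collinear
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    centre = np.array([ux, uy])
    return centre, float(np.linalg.norm(centre - a))


def _in_circle(circle: tuple[np.ndarray, float], p: np.ndarray) -> bool:
    centre, r = circle
    return float(np.linalg.norm(p - centre)) <= r * (1.0 + 1e-12) + _EPS


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest circle containing every point (Welzl, move-to-front).

    Returns ``(centre, radius)``.  Deterministic: the internal permutation
    uses a fixed seed, so identical inputs give identical output.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    pts = np.unique(pts, axis=0)
    n = len(pts)
    if n == 1:
        return pts[0].copy(), 0.0
    # fixed-seed permutation: expected-linear behaviour on points in convex
    # position (the common input here) while staying fully deterministic
    pts = pts[np.random.default_rng(1234).permutation(n)]

    circle = _circle_from_two(pts[0], pts[1])
    for i in range(2, n):
        if _in_circle(circle, pts[i]):
            continue
        # pts[i] lies on the boundary of the minimal circle of pts[:i+1]
        circle = (pts[i].copy(), 0.0)
        for j in range(i):
            if _in_circle(circle, pts[j]):
                continue
            circle = _circle_from_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(circle, pts[k]):
                    continue
                c3 = _circle_from_three(pts[i], pts[j], pts[k])
                if c3 is None:
                    # collinear support: widest pair circle covering the third
                    for a, b, c in ((pts[i], pts[j], pts[k]),
                                    (pts[i], pts[k], pts[j]),
                                    (pts[j], pts[k], pts[i])):
                        cand = _circle_from_two(a, b)
                        if _in_circle(cand, c):
                            c3 = cand
                            break
                if c3 is not None:
                    circle = c3
    return circle


def polygon_perimeter(vertices: np.ndarray) -> float:
    """Arc length of a closed polygon (first vertex not repeated)."""
    v = np.asarray(vertices, dtype=float)
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
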