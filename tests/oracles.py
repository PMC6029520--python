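"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the basis recursion
is re-written directly from the defining recurrence, the Delaunay oracle
tests every triple against the empty-circumcircle property, and nearest
neighbours are found by linear scan.
"""

from __future__ import annotations

import itertools

import numpy as np


def cox_de_boor(i: int, k: int, u: float, t: np.ndarray) -> float:
    """Textbook recursive basis evaluation with 0/0 treated as 0."""
    if k == 0:
        if t[i] <= u < t[i + 1]:
            return 1.0
        if u == t[i + 1] == t[-1] and t[i] < t[i + 1]:
            return 1.0
        return 0.0
    out = 0.0
    if t[i + k] != t[i]:
        out += (u - t[i]) / (t[i + k] - t[i]) * cox_de_boor(i, k - 1, u, t)
    if t[i + k + 1] != t[i + 1]:
        out += (t[i + k + 1] - u) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(i + 1, k - 1, u, t)
    return out


def brute_delaunay_edges(pts: np.ndarray, degen_tol: float = 1e-9) -> set | None:
    """Edge set of the Delaunay triangulation by O(n^4) circumcircle tests.

    Returns None when a near-cocircular degeneracy makes the answer
    ambiguous at floating-point precision.
    """
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-14:
            continue
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        cc = np.array([ux, uy])
        r = np.linalg.norm(a - cc)
        dist = np.linalg.norm(pts - cc, axis=1)
        mask = np.ones(n, bool)
        mask[[i, j, k]] = False
        if np.any(np.abs(dist[mask] - r) < degen_tol * max(r, 1.0)):
            return None  # cocircular degeneracy: oracle declines to answer
        if np.all(dist[mask] > r):
            edges |= {tuple(sorted(p)) for p in ((i, j), (i, k), (j, k))}
    return edges


def random_pslg(rng: np.random.Generator, n: int = 50, k: int = 10):
    """Random vertex set with k non-crossing constrained edges."""
    pts = rng.random((n, 2))

    def crosses(e1, e2):
        a, b = pts[e1[0]], pts[e1[1]]
        c, d = pts[e2[0]], pts[e2[1]]

        def o(u, v, w):
            return (v[0] - u[0]) * (w[1] - u[1]) - (v[1] - u[1]) * (w[0] - u[0])

        return o(a, b, c) * o(a, b, d) < 0 and o(c, d, a) * o(c, d, b) < 0

    cons: list[tuple[int, int]] = []
    tries = 0
    while len(cons) < k and tries < 2000:
        tries += 1
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        e = (int(i), int(j))
        if any(set(e) & set(c) for c in cons):
            continue
        if any(crosses(e, c) for c in cons):
            continue
        cons.append(e)
    return pts, cons


def brute_nearest(cloud: np.ndarray, p: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(cloud - p, axis=1)))


def _point_segment_distance(p, a, b):
    d = b - a
    t = np.clip((p - a) @ d / max(d @ d, 1e-300), 0.0, 1.0)
    return float(np.linalg.norm(a + t * d - p))


def point_triangle_distance_simple(p, a, b, c) -> float:
    """Closest-point distance by plane projection + the three edges.

    The closest point is either the orthogonal projection (when it lands
    inside the triangle) or lies on one of the edges; both cases are covered
    without any region-classification logic.
    """
    n = np.cross(b - a, c - a)
    nn = n @ n
    best = min(_point_segment_distance(p, a, b),
               _point_segment_distance(p, b, c),
               _point_segment_distance(p, c, a))
    if nn > 1e-300:
        q = p - ((p - a) @ n / nn) * n
        # barycentric inside test
        v0, v1, v2 = c - a, b - a, q - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if abs(den) > 1e-300:
            u = (d11 * d20 - d01 * d21) / den
            v = (d00 * d21 - d01 * d20) / den
            if u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12:
                best = min(best, float(np.linalg.norm(q - p)))
    return best


def brute_cloud_to_mesh(cloud: np.ndarray, verts: np.ndarray,
                        tris: np.ndarray) -> np.ndarray:
    """Exhaustive min over all point-triangle pairs."""
    out = np.empty(len(cloud))
    for i, p in enumerate(cloud):
        out[i] = min(point_triangle_distance_simple(p, verts[t[0]], verts[t[1]],
                                                    verts[t[2]]) for t in tris)
    return out
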