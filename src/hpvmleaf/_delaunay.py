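"""Divide-and-conquer Delaunay triangulation with constrained-edge insertion.

The unconstrained triangulation follows the classical quad-edge
divide-and-conquer scheme: vertices are sorted by u-coordinate into
single-vertex strips which are pasted together pairwise, giving the optimal
O(n log n) behaviour.  Constrained edges are then enforced by removing the
edges each constraint crosses and retriangulating the two resulting cavities
with the circumcircle rule, which leaves every unconstrained edge locally
Delaunay with respect to visible vertices.

Predicates use floating point with an exact rational fallback near zero, so
ties are resolved consistently.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

__all__ = ["delaunay_triangles", "constrained_delaunay"]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# geometric predicates
# ---------------------------------------------------------------------------

def _orient_det(pts, a: int, b: int, c: int) -> float:
    ax, ay = pts[a]
    bx, by = pts[b]
    cx, cy = pts[c]
    det = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    scale = max(abs(bx - ax), abs(by - ay), abs(cx - ax), abs(cy - ay), 1e-300)
    if abs(det) > _EPS * scale * scale:
        return det
    fax, fay = Fraction(float(ax)), Fraction(float(ay))
    d = ((Fraction(float(bx)) - fax) * (Fraction(float(cy)) - fay)
         - (Fraction(float(by)) - fay) * (Fraction(float(cx)) - fax))
    return float(np.sign(d))


def _ccw(pts, a: int, b: int, c: int) -> bool:
    return _orient_det(pts, a, b, c) > 0


def _incircle_det(pts, a: int, b: int, c: int, d: int) -> float:
    """> 0 iff d lies strictly inside the circumcircle of CCW triangle abc."""
    dx, dy = pts[d]
    rows = []
    for v in (a, b, c):
        vx, vy = pts[v]
        ex, ey = vx - dx, vy - dy
        rows.append((ex, ey, ex * ex + ey * ey))
    det = (rows[0][0] * (rows[1][1] * rows[2][2] - rows[1][2] * rows[2][1])
           - rows[0][1] * (rows[1][0] * rows[2][2] - rows[1][2] * rows[2][0])
           + rows[0][2] * (rows[1][0] * rows[2][1] - rows[1][1] * rows[2][0]))
    scale = max(max(abs(r[0]), abs(r[1])) for r in rows)
    if abs(det) > _EPS * scale**4:
        return det
    fdx, fdy = Fraction(float(dx)), Fraction(float(dy))
    frows = []
    for v in (a, b, c):
        ex = Fraction(float(pts[v][0])) - fdx
        ey = Fraction(float(pts[v][1])) - fdy
        frows.append((ex, ey, ex * ex + ey * ey))
    fdet = (frows[0][0] * (frows[1][1] * frows[2][2] - frows[1][2] * frows[2][1])
            - frows[0][1] * (frows[1][0] * frows[2][2] - frows[1][2] * frows[2][0])
            + frows[0][2] * (frows[1][0] * frows[2][1] - frows[1][1] * frows[2][0]))
    return float(np.sign(fdet))


def _in_circumcircle(pts, a: int, b: int, c: int, d: int) -> bool:
    """d strictly inside the circumcircle of triangle abc (any orientation)."""
    if _ccw(pts, a, b, c):
        return _incircle_det(pts, a, b, c, d) > 0
    return _incircle_det(pts, a, c, b, d) > 0


# ---------------------------------------------------------------------------
# quad-edge structure
# ---------------------------------------------------------------------------

class _QEdge:
    __slots__ = ("org", "rot", "onext", "alive")

    def __init__(self) -> None:
        self.org = -1
        self.rot: _QEdge = None  # type: ignore[assignment]
        self.onext: _QEdge = None  # type: ignore[assignment]
        self.alive = True

    @property
    def sym(self) -> "_QEdge":
        return self.rot.rot

    @property
    def invrot(self) -> "_QEdge":
        return self.rot.rot.rot

    @property
    def dest(self) -> int:
        return self.sym.org

    @property
    def oprev(self) -> "_QEdge":
        return self.rot.onext.rot

    @property
    def lnext(self) -> "_QEdge":
        return self.invrot.onext.rot

    @property
    def rprev(self) -> "_QEdge":
        return self.sym.onext


def _make_edge(edges: list[_QEdge]) -> _QEdge:
    e0, e1, e2, e3 = _QEdge(), _QEdge(), _QEdge(), _QEdge()
    e0.rot, e1.rot, e2.rot, e3.rot = e1, e2, e3, e0
    e0.onext, e1.onext, e2.onext, e3.onext = e0, e3, e2, e1
    edges.append(e0)
    return e0


def _splice(a: _QEdge, b: _QEdge) -> None:
    alpha = a.onext.rot
    beta = b.onext.rot
    a.onext, b.onext = b.onext, a.onext
    alpha.onext, beta.onext = beta.onext, alpha.onext


def _connect(edges: list[_QEdge], a: _QEdge, b: _QEdge) -> _QEdge:
    e = _make_edge(edges)
    e.org = a.dest
    e.sym.org = b.org
    _splice(e, a.lnext)
    _splice(e.sym, b)
    return e


def _delete_edge(e: _QEdge) -> None:
    _splice(e, e.oprev)
    _splice(e.sym, e.sym.oprev)
    for q in (e, e.rot, e.sym, e.invrot):
        q.alive = False


def _dc(pts, order: list[int], edges: list[_QEdge]) -> tuple[_QEdge, _QEdge]:
    n = len(order)
    if n == 2:
        a = _make_edge(edges)
        a.org, a.sym.org = order[0], order[1]
        return a, a.sym
    if n == 3:
        p1, p2, p3 = order
        a = _make_edge(edges)
        b = _make_edge(edges)
        _splice(a.sym, b)
        a.org, a.sym.org = p1, p2
        b.org, b.sym.org = p2, p3
        if _ccw(pts, p1, p2, p3):
            _connect(edges, b, a)
            return a, b.sym
        if _ccw(pts, p1, p3, p2):
            c = _connect(edges, b, a)
            return c.sym, c
        return a, b.sym  # collinear

    half = n // 2
    ldo, ldi = _dc(pts, order[:half], edges)
    rdi, rdo = _dc(pts, order[half:], edges)

    # lower common tangent
    while True:
        if _ccw(pts, rdi.org, ldi.org, ldi.dest):
            ldi = ldi.lnext
        elif _ccw(pts, ldi.org, rdi.dest, rdi.org):
            rdi = rdi.rprev
        else:
            break
    basel = _connect(edges, rdi.sym, ldi)
    if ldi.org == ldo.org:
        ldo = basel.sym
    if rdi.org == rdo.org:
        rdo = basel

    def valid(e: _QEdge) -> bool:
        return _ccw(pts, e.dest, basel.dest, basel.org)

    while True:
        lcand = basel.sym.onext
        if valid(lcand):
            while _incircle_det(pts, basel.dest, basel.org, lcand.dest,
                                lcand.onext.dest) > 0:
                t = lcand.onext
                _delete_edge(lcand)
                lcand = t
        rcand = basel.oprev
        if valid(rcand):
            while _incircle_det(pts, basel.dest, basel.org, rcand.dest,
                                rcand.oprev.dest) > 0:
                t = rcand.oprev
                _delete_edge(rcand)
                rcand = t
        lval, rval = valid(lcand), valid(rcand)
        if not lval and not rval:
            break
        if (not lval) or (rval and _incircle_det(pts, lcand.dest, lcand.org,
                                                 rcand.org, rcand.dest) > 0):
            basel = _connect(edges, rcand, basel.sym)
        else:
            basel = _connect(edges, basel.sym, lcand.sym)
    return ldo, rdo


def delaunay_triangles(points: np.ndarray) -> list[tuple[int, int, int]]:
    """CCW triangles of the Delaunay triangulation (strip divide-and-conquer).

    Raises ValueError for fewer than 3 points, duplicate points or an
    all-collinear configuration.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    order = sorted(range(n), key=lambda i: (pts[i, 0], pts[i, 1]))
    for i, j in zip(order, order[1:]):
        if pts[i, 0] == pts[j, 0] and pts[i, 1] == pts[j, 1]:
            raise ValueError(f"duplicate points at indices {i} and {j}")
    edges: list[_QEdge] = []
    import sys
    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 10000))
    try:
        _dc(pts, order, edges)
    finally:
        sys.setrecursionlimit(limit)

    tris: set[tuple[int, int, int]] = set()
    for e0 in edges:
        if not e0.alive:
            continue
        for e in (e0, e0.sym):
            a, b, c = e.org, e.dest, e.lnext.dest
            if e.lnext.lnext.dest != a:
                continue
            if _ccw(pts, a, b, c):
                m = min(a, b, c)
                if a == m:
                    tris.add((a, b, c))
                elif b == m:
                    tris.add((b, c, a))
                else:
                    tris.add((c, a, b))
    if not tris:
        raise ValueError("degenerate (collinear) point set has no triangulation")
    return sorted(tris)


# ---------------------------------------------------------------------------
# constrained-edge enforcement on a triangle soup
# ---------------------------------------------------------------------------

class _TriStore:
    """Directed-edge map of an oriented triangulation."""

    def __init__(self, pts: np.ndarray, tris: list[tuple[int, int, int]]) -> None:
        self.pts = pts
        self.apex: dict[tuple[int, int], int] = {}
        self.nbr: dict[int, set[int]] = {}
        for t in tris:
            self.add(*t)

    def add(self, a: int, b: int, c: int) -> None:
        if not _ccw(self.pts, a, b, c):
            a, b = b, a
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            self.apex[(u, v)] = w
            self.nbr.setdefault(u, set()).add(v)
            self.nbr.setdefault(v, set()).add(u)

    def remove(self, a: int, b: int, c: int) -> None:
        """Remove the CCW triangle (a, b, c); keys must match as stored."""
        for u, v in ((a, b), (b, c), (c, a)):
            self.apex.pop((u, v), None)
        for u, v in ((a, b), (b, c), (c, a)):
            if (u, v) not in self.apex and (v, u) not in self.apex:
                self.nbr.get(u, set()).discard(v)
                self.nbr.get(v, set()).discard(u)

    def has_edge(self, a: int, b: int) -> bool:
        return (a, b) in self.apex or (b, a) in self.apex

    def triangles(self) -> list[tuple[int, int, int]]:
        out = set()
        for (a, b), c in self.apex.items():
            m = min(a, b, c)
            if a == m:
                out.add((a, b, c))
            elif b == m:
                out.add((b, c, a))
            else:
                out.add((c, a, b))
        return sorted(out)


def _retriangulate_cavity(store: _TriStore, chain: list[int]) -> None:
    """CDT fill of a cavity bounded by the constraint and one side chain."""
    if len(chain) < 3:
        return
    s, t = chain[0], chain[-1]
    mids = chain[1:-1]
    c_idx = 0
    for k in range(1, len(mids)):
        if _in_circumcircle(store.pts, s, t, mids[c_idx], mids[k]):
            c_idx = k
    c = mids[c_idx]
    store.add(s, c, t)
    _retriangulate_cavity(store, chain[: c_idx + 2])
    _retriangulate_cavity(store, chain[c_idx + 1:])


def _insert_constraint(store: _TriStore, s: int, t: int) -> None:
    if s == t or store.has_edge(s, t):
        return
    pts = store.pts

    def side(v: int) -> float:
        return _orient_det(pts, s, t, v)

    # locate the triangle at s crossed by the segment
    start = None
    for x in list(store.nbr.get(s, ())):
        y = store.apex.get((s, x))
        if y is None:
            continue
        ox, oy = side(x), side(y)
        if ox == 0 and _between(pts, s, t, x):
            _insert_constraint(store, x, t)
            return
        if oy == 0 and _between(pts, s, t, y):
            _insert_constraint(store, y, t)
            return
        if ox < 0 and oy > 0:
            start = (x, y)
            break
    if start is None:
        raise ValueError(f"constraint ({s}, {t}) cannot be inserted (crossing or "
                         "inconsistent triangulation)")

    right, left = [start[0]], [start[1]]
    removed = [(s, start[0], start[1])]
    xr, yl = start
    while True:
        z = store.apex.get((yl, xr))
        if z is None:
            raise ValueError(f"constraint ({s}, {t}) walk left the triangulation")
        removed.append((yl, xr, z))
        if z == t:
            break
        oz = side(z)
        if oz == 0:
            # a vertex lies exactly on the segment: split the constraint
            _insert_constraint(store, s, z)
            _insert_constraint(store, z, t)
            return
        if oz < 0:
            right.append(z)
            xr = z
        else:
            left.append(z)
            yl = z

    for tri in removed:
        store.remove(*tri)
    store.nbr.setdefault(s, set()).add(t)
    store.nbr.setdefault(t, set()).add(s)
    _retriangulate_cavity(store, [s] + left + [t])
    _retriangulate_cavity(store, [t] + right[::-1] + [s])


def _between(pts, s: int, t: int, v: int) -> bool:
    lo = np.minimum(pts[s], pts[t])
    hi = np.maximum(pts[s], pts[t])
    return bool(np.all(pts[v] >= lo) and np.all(pts[v] <= hi))


def constrained_delaunay(points: np.ndarray,
                         constraints: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """CCW triangles of the constrained Delaunay triangulation."""
    pts = np.asarray(points, dtype=float)
    tris = delaunay_triangles(pts)
    if not constraints:
        return tris
    store = _TriStore(pts, tris)
    for s, t in constraints:
        _insert_constraint(store, int(s), int(t))
    return store.triangles()
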