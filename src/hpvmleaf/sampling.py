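"""Multi-scale point resampling of a leaf model.

Four steps, all governed by one configuration: (1) every skeleton curve is
divided at equal arc length l, curves shorter than alpha*l being ignored;
(2) samples are relaxed from low feature levels to high — a test point
closer than beta1*l to an already-fixed point is deleted, one between
beta1*l and beta2*l is re-inserted on its own curve at arc distance
(beta1+beta2)/2*l from the fixed point; (3) the leaf interior is filled by
an advancing front marching inward from the margin (vein polylines act as
interior barriers); (4) interior points are lifted to 3D and snapped to the
nearest scanned cloud point when one is close enough.

Distances in steps (2)-(3) are measured in metric-scaled uv coordinates
(parameter coordinates multiplied by the surface's mean derivative
magnitudes) so that l keeps its millimetre meaning in the parameter plane.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .hpvm import FeatureLevel, HPVMModel
from .splines import NURBSSurface, divide_by_arclength
from .surface import invert_points, metric_scale

__all__ = [
    "SamplingConfig",
    "CurveSamples",
    "FixedPoint",
    "FixedPointSet",
    "sample_curves",
    "relax_samples",
    "afm_fill",
    "calibrate_points",
    "margin_polygon_uv",
]

INTERIOR = "INTERIOR"


@dataclass(frozen=True)
class SamplingConfig:
    """Element size and the factors steering resampling.

    l is the target element size in mm; alpha the ignore factor; beta1 and
    beta2 the relaxing factors; h_factor the advancing-front height as a
    multiple of l (sqrt(3)/2 gives equilateral candidates); r_factor the
    node-reuse search radius as a multiple of l; snap_max the calibration
    snap threshold as a multiple of l.
    """

    l: float = 10.0
    alpha: float = 1.0
    beta1: float = 0.5
    beta2: float = 0.8
    h_factor: float = float(np.sqrt(3.0) / 2.0)
    r_factor: float = 0.7
    snap_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("element size l must be positive")
        if self.alpha < 0:
            raise ValueError("ignore factor alpha must be >= 0")
        if not 0 < self.beta1 < self.beta2:
            raise ValueError("relaxing factors must satisfy 0 < beta1 < beta2")
        if min(self.h_factor, self.r_factor, self.snap_max) <= 0:
            raise ValueError("h_factor, r_factor and snap_max must be positive")


@dataclass
class CurveSamples:
    """Equal-arc-length samples of one skeleton curve.

    uv coordinates are metric-scaled; a dense arc-length-parameterized
    polyline of the curve is kept so relaxation can re-insert points at
    prescribed arc distances without re-touching the surface.
    """

    curve_id: str
    level: FeatureLevel
    params: np.ndarray
    points_xyz: np.ndarray
    points_uv: np.ndarray            # metric-scaled uv
    points_uv_native: np.ndarray
    arc_s: np.ndarray                # arc-length coordinate of each sample
    inversion_ok: np.ndarray
    uv_scale: tuple[float, float] = (1.0, 1.0)
    anchor_mask: np.ndarray | None = None    # endpoints + junction anchors
    dense_s: np.ndarray = field(repr=False, default=None)
    dense_uv: np.ndarray = field(repr=False, default=None)
    dense_xyz: np.ndarray = field(repr=False, default=None)
    dense_uv_native: np.ndarray = field(repr=False, default=None)


@dataclass
class FixedPoint:
    uv: np.ndarray                   # metric-scaled
    uv_native: np.ndarray
    xyz: np.ndarray
    provenance: str                  # curve id or INTERIOR
    order: float                     # arc position along the source curve
    is_endpoint: bool = False


@dataclass
class FixedPointSet:
    points: list[FixedPoint]
    uv_scale: tuple[float, float]

    def by_curve(self, cid: str) -> list[FixedPoint]:
        return sorted((p for p in self.points if p.provenance == cid), key=lambda p: p.order)

    def uv_array(self) -> np.ndarray:
        return np.array([p.uv for p in self.points]).reshape(-1, 2)


def _attach_arcs(model: HPVMModel, cfg: SamplingConfig) -> dict[str, list[float]]:
    """Arc positions on each parent curve where a (sampled) child attaches."""
    out: dict[str, list[float]] = {}
    for ch in model.curves:
        if ch.parent_id is None or ch.attach_param is None:
            continue
        if ch.curve.arclength() < cfg.alpha * cfg.l:
            continue  # ignored child needs no junction anchor
        parent = model[ch.parent_id].curve
        edges, cum = parent._cumulative_arclength()
        out.setdefault(ch.parent_id, []).append(float(np.interp(ch.attach_param,
                                                                edges, cum)))
    return out


def sample_curves(model: HPVMModel, surface: NURBSSurface,
                  cfg: SamplingConfig) -> list[CurveSamples]:
    """Equal-arc-length samples of every curve not shorter than alpha*l.

    Junction points (where a sampled child curve attaches) are folded into
    the parent's sample set as anchors: a nearby equal-arc sample is moved
    onto the junction, otherwise the junction is inserted, so the discrete
    skeleton stays connected at vein branchings.
    """
    su, sw = metric_scale(surface)
    scale = np.array([su, sw])
    attach = _attach_arcs(model, cfg)
    out: list[CurveSamples] = []
    for c in model.curves:
        L = c.curve.arclength()
        if L < cfg.alpha * cfg.l:
            continue
        t_base = divide_by_arclength(c.curve, cfg.l)
        spacing = L / max(len(t_base) - 1, 1)
        s_list = list(spacing * np.arange(len(t_base)))
        anchors = {0.0, s_list[-1]}
        for s_a in sorted(attach.get(c.id, [])):
            if s_a <= 1e-9 or s_a >= L - 1e-9:
                continue  # coincides with a curve end, already an anchor
            i = int(np.argmin(np.abs(np.asarray(s_list) - s_a)))
            if abs(s_list[i] - s_a) < 0.35 * spacing and i not in (0, len(s_list) - 1) \
                    and s_list[i] not in anchors:
                s_list[i] = s_a
            else:
                s_list.append(s_a)
            anchors.add(s_a)
        s = np.array(sorted(s_list))
        t = c.curve.param_at_arclength(s)
        t[0], t[-1] = c.curve.domain
        anchor_mask = np.isin(s, sorted(anchors))
        xyz = np.atleast_2d(c.curve.evaluate(t))
        native, ok, _ = invert_points(surface, xyz)
        # dense polyline for relaxation re-insertion, seeded from the samples
        n_dense = int(np.clip(np.ceil(L / (cfg.l / 20.0)) + 1, len(t), 2000))
        s_d = np.linspace(0.0, L, n_dense)
        t_d = c.curve.param_at_arclength(s_d)
        xyz_d = np.atleast_2d(c.curve.evaluate(t_d))
        seeds = np.column_stack([np.interp(s_d, s, native[:, 0]),
                                 np.interp(s_d, s, native[:, 1])])
        native_d, _, _ = invert_points(surface, xyz_d, seeds=seeds)
        out.append(CurveSamples(
            curve_id=c.id, level=c.level, params=t, points_xyz=xyz,
            points_uv=native * scale, points_uv_native=native, arc_s=s,
            inversion_ok=ok, uv_scale=(su, sw), anchor_mask=anchor_mask,
            dense_s=s_d, dense_uv=native_d * scale, dense_xyz=xyz_d,
            dense_uv_native=native_d,
        ))
    return out


def _interp_dense(cs: CurveSamples, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    uv = np.array([np.interp(s, cs.dense_s, cs.dense_uv[:, k]) for k in range(2)])
    nat = np.array([np.interp(s, cs.dense_s, cs.dense_uv_native[:, k]) for k in range(2)])
    xyz = np.array([np.interp(s, cs.dense_s, cs.dense_xyz[:, k]) for k in range(3)])
    return uv, nat, xyz


def relax_samples(samples: list[CurveSamples], cfg: SamplingConfig) -> FixedPointSet:
    """Hierarchical relaxation: low levels fix first, higher levels yield.

    Curve start/end points are junction anchors and are never deleted.  A
    replaced point is positioned on its own curve at arc distance
    (beta1+beta2)/2*l from the projection of the nearest fixed point, toward
    the test point, and is itself re-checked against the beta1*l clearance.
    """
    b1 = cfg.beta1 * cfg.l
    mid = 0.5 * (cfg.beta1 + cfg.beta2) * cfg.l
    b2 = cfg.beta2 * cfg.l
    uv_scale = samples[0].uv_scale if samples else (1.0, 1.0)
    fixed: list[FixedPoint] = []
    fixed_uv: list[np.ndarray] = []

    def min_dist(p: np.ndarray) -> tuple[float, int]:
        if not fixed_uv:
            return np.inf, -1
        arr = np.asarray(fixed_uv)
        d = np.linalg.norm(arr - p, axis=1)
        i = int(np.argmin(d))
        return float(d[i]), i

    def push(fp: FixedPoint) -> None:
        fixed.append(fp)
        fixed_uv.append(fp.uv)

    for cs in sorted(samples, key=lambda c: (int(c.level), c.curve_id)):
        last = len(cs.arc_s) - 1
        for i, s in enumerate(cs.arc_s):
            p_uv = cs.points_uv[i]
            anchored = i in (0, last) or (cs.anchor_mask is not None
                                          and bool(cs.anchor_mask[i]))
            fp = FixedPoint(uv=p_uv.copy(), uv_native=cs.points_uv_native[i].copy(),
                            xyz=cs.points_xyz[i].copy(), provenance=cs.curve_id,
                            order=float(s), is_endpoint=anchored)
            if fp.is_endpoint:
                push(fp)
                continue
            d, j = min_dist(p_uv)
            if d >= b2:
                push(fp)
            elif d >= b1:
                # project the blocking fixed point onto this curve's polyline
                arr = cs.dense_uv
                k = int(np.argmin(np.linalg.norm(arr - fixed_uv[j], axis=1)))
                s_proj = float(cs.dense_s[k])
                sign = 1.0 if s > s_proj else -1.0
                s_new = s_proj + sign * mid
                if not 0.0 < s_new < cs.arc_s[-1]:
                    continue
                uv_n, nat_n, xyz_n = _interp_dense(cs, s_new)
                d2, _ = min_dist(uv_n)
                if d2 >= b1:
                    push(FixedPoint(uv=uv_n, uv_native=nat_n, xyz=xyz_n,
                                    provenance=cs.curve_id, order=s_new))
            # d < b1: deleted
    return FixedPointSet(points=fixed, uv_scale=uv_scale)


def margin_polygon_uv(fixed: FixedPointSet, model: HPVMModel) -> tuple[np.ndarray, list[int]]:
    """Ordered closed margin loop in metric-scaled uv (CCW), with indices
    into ``fixed.points``."""
    idx_of = {id(p): i for i, p in enumerate(fixed.points)}
    loop: list[int] = []
    for cid in model.margin_part_ids:
        part = fixed.by_curve(cid)
        for p in part:
            i = idx_of[id(p)]
            if loop:
                prev = fixed.points[loop[-1]]
                if np.linalg.norm(prev.uv - p.uv) < 1e-6:
                    continue
            loop.append(i)
    if len(loop) > 1:
        first, last = fixed.points[loop[0]], fixed.points[loop[-1]]
        if np.linalg.norm(first.uv - last.uv) < 1e-6:
            loop.pop()
    pts = np.array([fixed.points[i].uv for i in loop])
    # enforce CCW orientation
    area2 = float(np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]))
    if area2 < 0:
        loop = loop[::-1]
        pts = pts[::-1]
    return pts, loop


class _Grid:
    """Uniform hash grid for fixed-radius nearest-node queries."""

    def __init__(self, cell: float) -> None:
        self.cell = cell
        self.cells: dict[tuple[int, int], list[int]] = {}
        self.pts: list[np.ndarray] = []

    def add(self, p: np.ndarray) -> int:
        i = len(self.pts)
        self.pts.append(p)
        key = (int(np.floor(p[0] / self.cell)), int(np.floor(p[1] / self.cell)))
        self.cells.setdefault(key, []).append(i)
        return i

    def nearest_within(self, p: np.ndarray, r: float,
                       exclude: tuple[int, ...] = ()) -> int | None:
        cx, cy = int(np.floor(p[0] / self.cell)), int(np.floor(p[1] / self.cell))
        reach = int(np.ceil(r / self.cell))
        best, best_d = None, r
        for dx in range(-reach, reach + 1):
            for dy in range(-reach, reach + 1):
                for i in self.cells.get((cx + dx, cy + dy), ()):
                    if i in exclude:
                        continue
                    d = float(np.linalg.norm(self.pts[i] - p))
                    if d <= best_d:
                        best, best_d = i, d
        return best


def afm_fill(fixed: FixedPointSet, model: HPVMModel, surface: NURBSSurface,
             cfg: SamplingConfig, max_iter: int = 1_000_000) -> np.ndarray:
    """Advancing-front interior fill; returns accepted interior nodes.

    The closed margin loop is the initial front (marching inward); vein and
    ridge polylines are double-sided interior fronts.  The shortest active
    front is processed first: its candidate sits on the perpendicular
    bisector at height h_factor*l; an existing node within r_factor*l of the
    candidate replaces it.  Output is an (N, 2) array of metric-scaled uv
    interior nodes (an empty array when nothing fits).
    """
    loop_pts, loop_idx = margin_polygon_uv(fixed, model)
    if len(loop_pts) < 3:
        return np.empty((0, 2))
    poly = Polygon(loop_pts)
    h = cfg.h_factor * cfg.l
    r = cfg.r_factor * cfg.l

    grid = _Grid(cell=max(r, 1e-12))
    node_index: dict[int, int] = {}
    for i, p in enumerate(fixed.points):
        node_index[i] = grid.add(p.uv.astype(float))

    heap: list[tuple[float, int, int, int]] = []
    active: set[tuple[int, int]] = set()
    ever: set[tuple[int, int]] = set()
    counter = 0

    def add_front(a: int, b: int) -> None:
        nonlocal counter
        if a == b:
            return
        if (b, a) in active:
            active.discard((b, a))
            return
        if (a, b) in ever or (a, b) in active:
            return
        active.add((a, b))
        ever.add((a, b))
        length = float(np.linalg.norm(grid.pts[a] - grid.pts[b]))
        heapq.heappush(heap, (length, counter, a, b))
        counter += 1

    n_loop = len(loop_idx)
    for k in range(n_loop):
        add_front(node_index[loop_idx[k]], node_index[loop_idx[(k + 1) % n_loop]])
    idx_of = {id(p): i for i, p in enumerate(fixed.points)}
    for c in model.curves:
        if c.level == FeatureLevel.MARGIN:
            continue
        part = fixed.by_curve(c.id)
        for p, q in zip(part, part[1:]):
            a, b = node_index[idx_of[id(p)]], node_index[idx_of[id(q)]]
            add_front(a, b)
            add_front(b, a)

    interior: list[int] = []
    iters = 0
    while heap:
        iters += 1
        if iters > max_iter:
            raise RuntimeError(
                f"advancing front failed to terminate after {max_iter} iterations "
                f"({len(interior)} interior nodes, {len(active)} active fronts)"
            )
        _, _, a, b = heapq.heappop(heap)
        if (a, b) not in active:
            continue
        active.discard((a, b))
        pa, pb = grid.pts[a], grid.pts[b]
        d = pb - pa
        ln = float(np.linalg.norm(d))
        if ln < 1e-12:
            continue
        nrm = np.array([-d[1], d[0]]) / ln
        p0 = 0.5 * (pa + pb) + h * nrm
        if not shapely.contains_xy(poly, p0[0], p0[1]):
            continue
        near = grid.nearest_within(p0, r, exclude=(a, b))
        if near is not None:
            c = near
        else:
            c = grid.add(p0)
            interior.append(c)
        add_front(a, c)
        add_front(c, b)
    if not interior:
        return np.empty((0, 2))
    return np.array([grid.pts[i] for i in interior])


def calibrate_points(points_uv: np.ndarray, surface: NURBSSurface,
                     cloud: np.ndarray | None, cfg: SamplingConfig,
                     uv_scale: tuple[float, float] | None = None) -> np.ndarray:
    """Lift uv points to 3D and snap each to its nearest cloud point.

    Snapping only applies when the nearest scanned point lies within
    snap_max*l; otherwise the on-surface position is kept.  With no cloud the
    lift alone is returned.  ``uv_scale`` declares metric-scaled input uv.
    """
    pts = np.atleast_2d(np.asarray(points_uv, dtype=float))
    if pts.size == 0:
        return np.empty((0, 3))
    native = pts / np.asarray(uv_scale) if uv_scale is not None else pts
    lifted = surface.evaluate(native[:, 0], native[:, 1])
    if cloud is None or len(cloud) == 0:
        return lifted
    tree = cKDTree(np.asarray(cloud, dtype=float))
    dist, idx = tree.query(lifted)
    snap = dist <= cfg.snap_max * cfg.l
    out = lifted.copy()
    out[snap] = np.asarray(cloud)[idx[snap]]
    return out


def min_cross_curve_distance(fixed: FixedPointSet) -> float:
    """Smallest scaled-uv distance between fixed points of different curves,
    junction-anchored endpoints exempted."""
    pts = [p for p in fixed.points if not p.is_endpoint]
    best = np.inf
    for i, p in enumerate(pts):
        for q in pts[i + 1:]:
            if p.provenance == q.provenance:
                continue
            best = min(best, float(np.linalg.norm(p.uv - q.uv)))
    return best
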