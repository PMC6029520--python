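"""Synthetic palmate leaves with exact ground truth.

The generator emulates a scanned cucumber-like palmate leaf: a closed lobed
margin with sharp lobe tips and sinuses, a primary vein from base to apex,
secondary veins leaving the primary toward the margin, short tertiary veins,
wrinkle ridges near the lobe tips, a groove depression along the veins, an
overall blade fold, and a scanner-like noisy point cloud.  Every feature is
analytic, so the true surface area and the exact feature point sets are
available for parameter-recovery tests.

Geometry: the planform is an ellipse-based radius function modulated by a
triangular wave (kinks make the sharp points); the surface is a height field
z(x, y) over the planform; veins are polylines whose start points coincide
exactly with vertices of their parent polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .hpvm import FeatureLevel, FeaturePointSet

__all__ = ["LeafParams", "SyntheticLeaf", "SuiteBundle", "generate_leaf", "generate_suite"]

_WIDTH_RATIO = 0.85      # planform width / length of the bounding ellipse
_RIDGE_SPAN = (0.5, 0.9)  # radial fraction covered by a wrinkle ridge crest
_RIDGE_CENTER = 0.72
_RIDGE_WIDTH = 0.14
_GROOVE_SIGMA = 2.0       # mm, half-width of the vein groove depression


@dataclass(frozen=True)
class LeafParams:
    """Shape, structure and scan parameters of a synthetic leaf (mm)."""

    midvein_length: float = 140.0
    lobes: int = 5
    lobe_depth: float = 0.35
    n_secondary_per_side: int = 3
    n_tertiary_per_secondary: int = 2
    wrinkle_amplitude: float = 1.5
    vein_groove_depth: float = 0.8
    bend: float = 0.002          # curvature of the blade fold, 1/mm
    noise_sd: float = 0.12       # scanner noise, mm
    cloud_density: float = 1.0   # points per mm^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.midvein_length <= 0:
            raise ValueError("midvein_length must be positive")
        if self.lobes < 2:
            raise ValueError("need at least 2 lobes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.lobe_depth < 1:
            raise ValueError("lobe_depth must be in [0, 1)")


class _Planform:
    """Lobed closed margin r(theta) around an interior centre."""

    def __init__(self, p: LeafParams) -> None:
        self.p = p
        t_base = self._tri(np.array([-np.pi / 2]), p.lobes)[0]
        f_base = 1.0 - p.lobe_depth * t_base
        self.a_y = p.midvein_length / (1.0 + f_base)
        self.a_x = _WIDTH_RATIO * self.a_y
        self.center = np.array([0.0, self.a_y * f_base])

    @staticmethod
    def _tri(theta: np.ndarray, lobes: int) -> np.ndarray:
        phi = (theta - np.pi / 2) * lobes / (2 * np.pi)
        frac = phi - np.round(phi)
        return 2.0 * np.abs(frac)

    def radius(self, theta: np.ndarray) -> np.ndarray:
        rho = self.a_x * self.a_y / np.sqrt((self.a_y * np.cos(theta))**2
                                            + (self.a_x * np.sin(theta))**2)
        return rho * (1.0 - self.p.lobe_depth * self._tri(theta, self.p.lobes))

    def point(self, theta: np.ndarray) -> np.ndarray:
        r = self.radius(theta)
        return self.center + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)

    def kink_angles(self) -> np.ndarray:
        m = np.arange(2 * self.p.lobes)
        th = np.pi / 2 + np.pi * m / self.p.lobes
        return np.sort(np.mod(th + np.pi, 2 * np.pi) - np.pi)

    def tip_angles(self) -> np.ndarray:
        k = np.arange(self.p.lobes)
        th = np.pi / 2 + 2 * np.pi * k / self.p.lobes
        return np.mod(th + np.pi, 2 * np.pi) - np.pi

    def polygon(self, n: int = 1440) -> np.ndarray:
        th = np.linspace(-np.pi, np.pi, n, endpoint=False)
        return self.point(th)

    def implicit(self, xy: np.ndarray) -> np.ndarray:
        """< 0 inside the margin, > 0 outside."""
        d = np.atleast_2d(xy) - self.center
        r = np.linalg.norm(d, axis=1)
        th = np.arctan2(d[:, 1], d[:, 0])
        return r - self.radius(th)

    def ray_to_margin(self, start: np.ndarray, direction: np.ndarray) -> float:
        """Distance along a ray from an interior point to the margin."""
        direction = direction / np.linalg.norm(direction)
        t_hi = 4.0 * self.a_y
        ts = np.linspace(0.0, t_hi, 256)
        vals = self.implicit(start + ts[:, None] * direction)
        out = np.where(vals > 0)[0]
        if len(out) == 0:
            return t_hi
        hi = ts[out[0]]
        lo = ts[max(out[0] - 1, 0)]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self.implicit(np.array([start + mid * direction]))[0] > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)


class _HeightField:
    """Analytic z(x, y): blade fold + wrinkle ridges - vein grooves.

    Each wrinkle bump is tied to one ridge crest line (angle plus radial
    band): wrinkles exist exactly where the skeleton can express them.
    """

    def __init__(self, plan: _Planform, p: LeafParams,
                 vein_tree: cKDTree | None,
                 wrinkles: list[tuple[float, float, float]] | None = None) -> None:
        self.plan = plan
        self.p = p
        self.vein_tree = vein_tree
        self.wrinkles = wrinkles or []   # (angle, s_mid, s_halfwidth)
        self.sigma_ang = 0.35 * np.pi / p.lobes

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p, plan = self.p, self.plan
        z = 0.5 * p.bend * (y - plan.center[1])**2
        if p.wrinkle_amplitude > 0 and self.wrinkles:
            dx = x - plan.center[0]
            dy = y - plan.center[1]
            r = np.hypot(dx, dy)
            th = np.arctan2(dy, dx)
            s = r / np.maximum(plan.radius(th), 1e-12)
            for th_r, s_mid, s_half in self.wrinkles:
                ang = np.mod(th - th_r + np.pi, 2 * np.pi) - np.pi
                radial = np.exp(-(((s - s_mid) / max(s_half, 1e-6))**2))
                z = z + p.wrinkle_amplitude * np.exp(-(ang / self.sigma_ang)**2) * radial
        if p.vein_groove_depth > 0 and self.vein_tree is not None:
            pts = np.column_stack([np.ravel(x), np.ravel(y)])
            d, _ = self.vein_tree.query(pts)
            z = z - (p.vein_groove_depth
                     * np.exp(-0.5 * (d / _GROOVE_SIGMA)**2)).reshape(np.shape(z))
        return z

    def lift(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return np.column_stack([xy, self(xy[:, 0], xy[:, 1])])


@dataclass
class SyntheticLeaf:
    cloud: np.ndarray
    truth_sets: list[FeaturePointSet]
    true_area: float
    params: LeafParams
    planform_polygon: np.ndarray = field(repr=False, default=None)
    height: _HeightField = field(repr=False, default=None)

    def margin_polygon(self) -> Polygon:
        return Polygon(self.planform_polygon)


def _vein_polylines(plan: _Planform, p: LeafParams,
                    rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray],
                                                       list[np.ndarray]]:
    L = p.midvein_length
    n_s = p.n_secondary_per_side
    y_attach = L * np.clip(0.2 + 0.5 * np.arange(n_s) / max(n_s - 1, 1)
                           + rng.uniform(-0.02, 0.02, n_s), 0.08, 0.85)
    y_attach = np.sort(y_attach)
    ys = np.unique(np.r_[np.linspace(0.0, L, 41), y_attach, y_attach])
    primary = np.column_stack([np.zeros_like(ys), ys])

    secondaries: list[np.ndarray] = []
    for sgn in (+1.0, -1.0):
        for j in range(n_s):
            start = np.array([0.0, y_attach[j]])
            gamma = np.deg2rad(20.0 + 25.0 * j / max(n_s - 1, 1)
                               + rng.uniform(-4.0, 4.0))
            d = np.array([sgn * np.cos(gamma), np.sin(gamma)])
            t_star = plan.ray_to_margin(start, d)
            reach = 0.82 * t_star
            tau = np.linspace(0.0, 1.0, 13)
            perp = np.array([-d[1], d[0]])
            if perp[1] < 0:
                perp = -perp
            bulge = 0.06 * reach * np.sin(np.pi * tau)
            poly = start + np.outer(tau * reach, d) + np.outer(bulge, perp)
            secondaries.append(poly)

    tertiaries: list[np.ndarray] = []
    for si, sec in enumerate(secondaries):
        n_v = len(sec)
        ks = np.unique(np.round(np.linspace(0.3, 0.7, max(p.n_tertiary_per_secondary, 1))
                                * (n_v - 1)).astype(int))
        ks = ks[: p.n_tertiary_per_secondary]
        for m, k in enumerate(ks):
            start = sec[k].copy()
            seg = sec[min(k + 1, n_v - 1)] - sec[max(k - 1, 0)]
            seg = seg / np.linalg.norm(seg)
            ang = np.deg2rad(50.0 + rng.uniform(-6.0, 6.0)) * (1 if (m + si) % 2 == 0 else -1)
            ca, sa = np.cos(ang), np.sin(ang)
            d = np.array([ca * seg[0] - sa * seg[1], sa * seg[0] + ca * seg[1]])
            sec_len = float(np.sum(np.linalg.norm(np.diff(sec, axis=0), axis=1)))
            t_star = plan.ray_to_margin(start, d)
            length = min(0.25 * sec_len, 0.6 * t_star)
            tau = np.linspace(0.0, 1.0, 7)
            poly = start + np.outer(tau * length, d)
            # a tertiary stops short of any other vein it approaches; its own
            # parent is excluded because the start sits on it
            others = [primary, *(s2 for k2, s2 in enumerate(secondaries) if k2 != si),
                      *tertiaries]
            poly = _trim_at_crossings(poly, others)
            if poly is not None:
                poly = _clearance_trim(poly, others, clearance=7.0, min_len=5.0,
                                       keep="start")
            if poly is not None:
                tertiaries.append(poly)
    return primary, secondaries, tertiaries


def _first_crossing_arc(poly: np.ndarray, others: list[np.ndarray],
                        s_min: float = 1.0) -> float | None:
    """Arc position of the first proper crossing with any other polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s0 = np.r_[0.0, np.cumsum(seg)]
    best: float | None = None
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        for other in others:
            for j in range(len(other) - 1):
                c, d = other[j], other[j + 1]
                r = b - a
                s = d - c
                den = r[0] * s[1] - r[1] * s[0]
                if abs(den) < 1e-14:
                    continue
                qp = c - a
                t = (qp[0] * s[1] - qp[1] * s[0]) / den
                u = (qp[0] * r[1] - qp[1] * r[0]) / -den
                if 1e-9 < t < 1 - 1e-9 and 1e-9 < u < 1 - 1e-9:
                    s_hit = s0[i] + t * seg[i]
                    if s_hit > s_min and (best is None or s_hit < best):
                        best = s_hit
    return best


def _trim_at_crossings(poly: np.ndarray, others: list[np.ndarray],
                       gap: float = 8.0, min_len: float = 6.0) -> np.ndarray | None:
    """Cut a feature polyline short of its first crossing; None if too short."""
    s_hit = _first_crossing_arc(poly, others)
    if s_hit is None:
        return poly
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s0 = np.r_[0.0, np.cumsum(seg)]
    s_cut = s_hit - gap
    if s_cut < min_len:
        return None
    si = np.linspace(0.0, s_cut, len(poly))
    return np.column_stack([np.interp(si, s0, poly[:, 0]),
                            np.interp(si, s0, poly[:, 1])])


def _densify(poly: np.ndarray, step: float = 0.5) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    si = np.linspace(0.0, s[-1], max(int(np.ceil(s[-1] / step)), len(poly)))
    return np.column_stack([np.interp(si, s, poly[:, 0]), np.interp(si, s, poly[:, 1])])


def _clearance_trim(poly: np.ndarray, others: list[np.ndarray], clearance: float,
                    min_len: float, keep: str = "longest") -> np.ndarray | None:
    """Keep the part of a feature polyline at least ``clearance`` from others.

    keep='start' cuts at the first too-close point (for lines anchored at
    their start); keep='longest' retains the longest clear run.  Returns
    None when nothing of at least ``min_len`` mm remains.
    """
    if not others:
        return poly
    tree = cKDTree(np.vstack([_densify(o) for o in others]))
    dense = _densify(poly, step=0.5)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    ok = tree.query(dense)[0] >= clearance
    if keep == "start":
        bad = np.where(~ok)[0]
        hi = len(dense) - 1 if len(bad) == 0 else max(bad[0] - 1, 0)
        lo = 0
    else:
        best_lo = best_hi = -1
        run_lo = None
        for i, flag in enumerate(np.r_[ok, False]):
            if flag and run_lo is None:
                run_lo = i
            elif not flag and run_lo is not None:
                if best_lo < 0 or s[i - 1] - s[run_lo] > s[best_hi] - s[best_lo]:
                    best_lo, best_hi = run_lo, i - 1
                run_lo = None
        if best_lo < 0:
            return None
        lo, hi = best_lo, best_hi
    if s[hi] - s[lo] < min_len:
        return None
    si = np.linspace(s[lo], s[hi], len(poly))
    return np.column_stack([np.interp(si, s, dense[:, 0]),
                            np.interp(si, s, dense[:, 1])])


def generate_leaf(params: LeafParams | None = None) -> SyntheticLeaf:
    """Deterministic synthetic leaf: cloud, truth feature sets, true area."""
    p = params or LeafParams()
    rng = np.random.default_rng(p.seed)
    plan = _Planform(p)

    primary, secondaries, tertiaries = _vein_polylines(plan, p, rng)
    dense_veins = []
    for poly in [primary, *secondaries, *tertiaries]:
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        n = max(int(np.ceil(seg.sum() / 0.5)), len(poly))
        s = np.r_[0.0, np.cumsum(seg)]
        si = np.linspace(0.0, s[-1], n)
        dense_veins.append(np.column_stack([np.interp(si, s, poly[:, 0]),
                                            np.interp(si, s, poly[:, 1])]))
    vein_tree = cKDTree(np.vstack(dense_veins)) if p.vein_groove_depth > 0 else None

    # ridge crest lines (between lobe tip and sinus, well clear of veins);
    # each surviving crest defines one wrinkle bump of the height field
    veins_2d = [primary, *secondaries, *tertiaries]
    ridges_2d: list[np.ndarray] = []
    wrinkles: list[tuple[float, float, float]] = []
    for th_tip in plan.tip_angles():
        th_r = th_tip + 0.45 * np.pi / p.lobes
        s = np.linspace(*_RIDGE_SPAN, 9)
        d = np.array([np.cos(th_r), np.sin(th_r)])
        rad = plan.radius(np.full(1, th_r))[0]
        pts2 = plan.center + np.outer(s * rad, d)
        pts2 = _clearance_trim(pts2, veins_2d, clearance=12.0, min_len=8.0)
        if pts2 is None:
            continue
        ridges_2d.append(pts2)
        s_lo = np.linalg.norm(pts2[0] - plan.center) / rad
        s_hi = np.linalg.norm(pts2[-1] - plan.center) / rad
        wrinkles.append((th_r, 0.5 * (s_lo + s_hi), 0.45 * (s_hi - s_lo)))

    height = _HeightField(plan, p, vein_tree, wrinkles)

    sets: list[FeaturePointSet] = []
    kinks = plan.kink_angles()
    for i in range(len(kinks)):
        th0 = kinks[i]
        th1 = kinks[(i + 1) % len(kinks)]
        if th1 <= th0:
            th1 += 2 * np.pi
        th = np.linspace(th0, th1, 21)
        pts = height.lift(plan.point(th))
        roles = ["sharp"] + ["none"] * (len(pts) - 2) + ["sharp"]
        sets.append(FeaturePointSet(level=FeatureLevel.MARGIN, points=pts, roles=roles))
    for pts2 in ridges_2d:
        sets.append(FeaturePointSet(level=FeatureLevel.RIDGE, points=height.lift(pts2)))
    sets.append(FeaturePointSet(level=FeatureLevel.PRIMARY, points=height.lift(primary)))
    for sec in secondaries:
        sets.append(FeaturePointSet(level=FeatureLevel.SECONDARY, points=height.lift(sec)))
    for ter in tertiaries:
        sets.append(FeaturePointSet(level=FeatureLevel.TERTIARY, points=height.lift(ter)))

    polygon = plan.polygon()
    poly = Polygon(polygon)

    # stratified cloud sampling: one jittered point per grid cell
    cell = 1.0 / np.sqrt(max(p.cloud_density, 1e-12))
    minx, miny, maxx, maxy = poly.bounds
    nx = max(int(np.ceil((maxx - minx) / cell)), 1)
    ny = max(int(np.ceil((maxy - miny) / cell)), 1)
    gx, gy = np.meshgrid(minx + cell * np.arange(nx), miny + cell * np.arange(ny))
    pts = np.column_stack([gx.ravel(), gy.ravel()]) + rng.random((nx * ny, 2)) * cell
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    cloud = height.lift(pts)
    if p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd, size=cloud.shape)
        norm = np.linalg.norm(noise, axis=1)
        bad = norm > 3.0 * p.noise_sd
        while bad.any():  # truncate at 3 sigma so the cloud stays near the surface
            noise[bad] = rng.normal(0.0, p.noise_sd, size=(int(bad.sum()), 3))
            norm = np.linalg.norm(noise, axis=1)
            bad = norm > 3.0 * p.noise_sd
        cloud = cloud + noise

    true_area = _analytic_area(polygon, height)
    return SyntheticLeaf(cloud=cloud, truth_sets=sets, true_area=true_area, params=p,
                         planform_polygon=polygon, height=height)


def _analytic_area(polygon: np.ndarray, height: _HeightField,
                   grid_step: float = 1.0) -> float:
    """Surface area by dense triangulated quadrature over the planform."""
    from scipy.spatial import Delaunay

    poly = Polygon(polygon)
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx, grid_step)
    ys = np.arange(miny, maxy, grid_step)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(poly, grid[:, 0], grid[:, 1])
    pts2 = np.vstack([polygon, grid[inside]])
    tri = Delaunay(pts2)
    cent = pts2[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    sim = tri.simplices[keep]
    xyz = height.lift(pts2)
    a, b, c = xyz[sim[:, 0]], xyz[sim[:, 1]], xyz[sim[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


@dataclass
class SuiteBundle:
    """One leaf plus a run configuration per element size."""

    leaf: SyntheticLeaf
    sizes: list[float]
    configs: list  # SamplingConfig per size


def generate_suite(sizes: list[float], params: LeafParams | None = None) -> SuiteBundle:
    """Shared leaf and one sampling configuration per element size."""
    from .sampling import SamplingConfig

    if not sizes:
        raise ValueError("sizes must be non-empty")
    p = params or LeafParams()
    leaf = generate_leaf(p)
    cfgs = [SamplingConfig(l=float(s), seed=p.seed) for s in sizes]
    return SuiteBundle(leaf=leaf, sizes=[float(s) for s in sizes], configs=cfgs)
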