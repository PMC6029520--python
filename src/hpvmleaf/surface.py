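"""Auxiliary NURBS membrane of the leaf.

The smooth surface bounded (in practice) by the margin and passing close to
every skeleton curve.  Constraint points sampled densely from the HPVM
curves are parameterized by an affine normalisation of their coordinates in
the skeleton's principal (planform) plane, and the control net is solved by
weighted least squares with a second-difference smoothing penalty.  The
surface's own parameter rectangle is the uv domain used by all downstream
sampling and meshing; margin samples map near the rectangle boundary because
the planform fills its bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay as _SciDelaunay

from .hpvm import FeatureLevel, HPVMModel
from .splines import NURBSSurface, _basis_matrix, clamped_uniform_knots

__all__ = [
    "SurfaceFit",
    "UVPoint",
    "eval_surface",
    "fit_auxiliary_surface",
    "invert_point",
    "invert_points",
    "metric_scale",
    "surface_area",
]

_PAD = 0.02  # fraction of the parameter rectangle kept clear of constraints


@dataclass
class UVPoint:
    """A location in the surface parameter domain."""

    u: float
    w: float
    converged: bool = True
    distance: float = 0.0


@dataclass
class SurfaceFit:
    surface: NURBSSurface
    constraint_residuals: np.ndarray     # mm, one per constraint point
    boundary_residual: float             # mm, max over margin constraints
    constraint_uv: np.ndarray            # (N, 2) parameters assigned to constraints
    constraint_curve_ids: list[str]
    plane_origin: np.ndarray
    plane_axes: np.ndarray               # (2, 3) planform axes
    uv_offset: np.ndarray                # planform -> uv affine map
    uv_scale: np.ndarray

    @property
    def max_residual(self) -> float:
        return float(self.constraint_residuals.max())


def eval_surface(surface: NURBSSurface, u, w) -> np.ndarray:
    """Rational tensor-product surface point(s); see NURBSSurface.evaluate."""
    return surface.evaluate(u, w)


def _principal_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    origin = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - origin, full_matrices=False)
    axes = vt[:2]
    # deterministic orientation: largest-magnitude component positive
    for k in range(2):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    return origin, axes


def fit_auxiliary_surface(model: HPVMModel, net_size: tuple[int, int] = (15, 15),
                          vein_weight: float = 2.0, degree: int = 3,
                          smoothing: float = 1e-2, margin_weight: float = 10.0,
                          samples_per_mm: float = 0.5) -> SurfaceFit:
    """Weighted least-squares NURBS fit constrained by all HPVM curves.

    Margin constraint points carry the fixed ``margin_weight``; vein and
    ridge points carry ``vein_weight`` (>= 1 emphasises veins).  ``smoothing``
    scales a second-difference (thin-plate-like) penalty on the control net
    that also regularises the corners of the rectangle outside the leaf.
    """
    m, n = net_size
    if m < 4 or n < 4:
        raise ValueError("net_size must be at least (4, 4)")
    pts_list, wt_list, ids = [], [], []
    for c in model.curves:
        L = c.curve.arclength()
        npts = int(np.clip(L * samples_per_mm, 16, 200))
        lo, hi = c.curve.domain
        p = c.curve.evaluate(np.linspace(lo, hi, npts))
        pts_list.append(p)
        wt_list.append(np.full(npts, margin_weight if c.level == FeatureLevel.MARGIN
                               else float(vein_weight)))
        ids.extend([c.id] * npts)
    pts = np.vstack(pts_list)
    wts = np.concatenate(wt_list)
    if len(pts) < m * n:
        raise ValueError(
            f"underdetermined surface fit: {len(pts)} constraints for a {m}x{n} net; "
            "use a smaller net"
        )

    origin, axes = _principal_plane(pts)
    plan = (pts - origin) @ axes.T                     # (N, 2) planform coords
    lo2, hi2 = plan.min(axis=0), plan.max(axis=0)
    span = np.maximum(hi2 - lo2, 1e-12)
    uv_scale = (1.0 - 2 * _PAD) / span
    uv_offset = _PAD - lo2 * uv_scale
    uv = plan * uv_scale + uv_offset                   # in (PAD, 1-PAD)

    knots_u = clamped_uniform_knots(m, degree)
    knots_w = clamped_uniform_knots(n, degree)
    Bu = _basis_matrix(uv[:, 0], knots_u.values, degree)
    Bw = _basis_matrix(uv[:, 1], knots_w.values, degree)
    A = np.einsum("pi,pj->pij", Bu, Bw).reshape(len(pts), m * n)

    AtWA = (A * wts[:, None]).T @ A
    AtWb = (A * wts[:, None]).T @ pts
    # second-difference penalty along both net directions
    Du = np.diff(np.eye(m), n=2, axis=0)
    Dw = np.diff(np.eye(n), n=2, axis=0)
    P = np.kron(Du.T @ Du, np.eye(n)) + np.kron(np.eye(m), Dw.T @ Dw)
    lam = smoothing * np.trace(AtWA) / (m * n)
    net = np.linalg.solve(AtWA + lam * P + 1e-14 * np.trace(AtWA) * np.eye(m * n), AtWb)

    surf = NURBSSurface(control_net=net.reshape(m, n, 3), weights=np.ones((m, n)),
                        degree_u=degree, degree_w=degree,
                        knots_u=knots_u, knots_w=knots_w)
    fitted = surf.evaluate(uv[:, 0], uv[:, 1])
    resid = np.linalg.norm(fitted - pts, axis=1)
    is_margin = np.array([model[cid].level == FeatureLevel.MARGIN for cid in ids])
    boundary = float(resid[is_margin].max()) if is_margin.any() else 0.0
    return SurfaceFit(surface=surf, constraint_residuals=resid, boundary_residual=boundary,
                      constraint_uv=uv, constraint_curve_ids=ids, plane_origin=origin,
                      plane_axes=axes, uv_offset=uv_offset, uv_scale=uv_scale)


def _seed_grid(surface: NURBSSurface, n: int = 41) -> tuple[np.ndarray, np.ndarray]:
    cache = getattr(surface, "_inversion_seed_cache", None)
    if cache is not None and cache[0].shape[0] == n * n:
        return cache[1], cache[2]
    (ulo, uhi), (wlo, whi) = surface.domain_u, surface.domain_w
    uu, ww = np.meshgrid(np.linspace(ulo, uhi, n), np.linspace(wlo, whi, n), indexing="ij")
    uv = np.column_stack([uu.ravel(), ww.ravel()])
    xyz = surface.evaluate(uv[:, 0], uv[:, 1])
    surface._inversion_seed_cache = (xyz, uv, xyz)  # type: ignore[attr-defined]
    return uv, xyz


def invert_point(surface: NURBSSurface, p: np.ndarray, tol: float = 1e-6,
                 max_iter: int = 40, seed_uv: tuple[float, float] | None = None) -> UVPoint:
    """Parameters (u, w) minimising ||S(u,w) - p|| (seeded Gauss-Newton).

    Off-surface points return the parameters of the foot point; results that
    fail to converge are flagged, never raised.  ``seed_uv`` warm-starts the
    search (used when inverting consecutive points of one curve).
    """
    p = np.asarray(p, dtype=float)
    if seed_uv is not None:
        u, w = float(seed_uv[0]), float(seed_uv[1])
    else:
        uv_grid, xyz_grid = _seed_grid(surface)
        i = int(np.argmin(np.einsum("ij,ij->i", xyz_grid - p, xyz_grid - p)))
        u, w = uv_grid[i]
    (ulo, uhi), (wlo, whi) = surface.domain_u, surface.domain_w
    r = surface.evaluate(u, w) - p
    f = float(r @ r)
    converged = False
    for _ in range(max_iter):
        su, sw = surface.partials(u, w)
        su, sw = su[0], sw[0]
        J = np.column_stack([su, sw])
        g = J.T @ r
        H = J.T @ J + 1e-12 * np.eye(2)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        # damped update with domain clamping
        scale = 1.0
        improved = False
        for _ in range(20):
            u1 = float(np.clip(u + scale * step[0], ulo, uhi))
            w1 = float(np.clip(w + scale * step[1], wlo, whi))
            r1 = surface.evaluate(u1, w1) - p
            f1 = float(r1 @ r1)
            if f1 <= f:
                improved = f1 < f - 1e-30
                u, w, r, f = u1, w1, r1, f1
                break
            scale *= 0.5
        gnorm = float(np.linalg.norm(g))
        span = max(uhi - ulo, whi - wlo)
        if gnorm < 1e-12 * max(1.0, f) or (not improved and gnorm * span < 1e-9):
            converged = True
            break
        if not improved:
            break
    # projected-gradient stationarity also counts as converged at the boundary
    if not converged:
        converged = float(np.sqrt(f)) <= tol
    return UVPoint(u=float(u), w=float(w), converged=bool(converged),
                   distance=float(np.sqrt(f)))


def invert_points(surface: NURBSSurface, pts: np.ndarray, tol: float = 1e-6,
                  max_iter: int = 40,
                  seeds: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray,
                                                            np.ndarray]:
    """Batched foot-point inversion: (uv (N,2), converged (N,), distance (N,)).

    Same damped Gauss-Newton as :func:`invert_point` but iterated on whole
    arrays, which is what the curve samplers use.
    """
    P = np.atleast_2d(np.asarray(pts, dtype=float))
    n = len(P)
    (ulo, uhi), (wlo, whi) = surface.domain_u, surface.domain_w
    if seeds is None:
        uv_grid, xyz_grid = _seed_grid(surface)
        seeds_arr = np.empty((n, 2))
        for k0 in range(0, n, 512):
            blk = P[k0:k0 + 512]
            d2 = ((blk[:, None, :] - xyz_grid[None, :, :])**2).sum(axis=2)
            seeds_arr[k0:k0 + 512] = uv_grid[np.argmin(d2, axis=1)]
    else:
        seeds_arr = np.array(seeds, dtype=float).reshape(n, 2)
    u = seeds_arr[:, 0].copy()
    w = seeds_arr[:, 1].copy()
    r = surface.evaluate(u, w) - P
    f = np.einsum("ij,ij->i", r, r)
    span = max(uhi - ulo, whi - wlo)
    for _ in range(max_iter):
        su, sw = surface.partials(u, w)
        g1 = np.einsum("ij,ij->i", su, r)
        g2 = np.einsum("ij,ij->i", sw, r)
        h11 = np.einsum("ij,ij->i", su, su) + 1e-12
        h12 = np.einsum("ij,ij->i", su, sw)
        h22 = np.einsum("ij,ij->i", sw, sw) + 1e-12
        det = np.maximum(h11 * h22 - h12**2, 1e-30)
        du = -(h22 * g1 - h12 * g2) / det
        dw = -(h11 * g2 - h12 * g1) / det
        scale = np.ones(n)
        active = np.ones(n, dtype=bool)
        for _ in range(15):
            u1 = np.clip(u + scale * du, ulo, uhi)
            w1 = np.clip(w + scale * dw, wlo, whi)
            r1 = surface.evaluate(u1, w1) - P
            f1 = np.einsum("ij,ij->i", r1, r1)
            better = f1 <= f
            upd = active & better
            u[upd], w[upd], f[upd] = u1[upd], w1[upd], f1[upd]
            r[upd] = r1[upd]
            active = active & ~better
            if not active.any():
                break
            scale[active] *= 0.5
        gnorm = np.hypot(g1, g2)
        if np.all(gnorm * span < 1e-9 * np.maximum(1.0, f) + 1e-15):
            break
    gn_final = np.hypot(g1, g2)
    dist = np.sqrt(f)
    converged = (gn_final * span < 1e-6 * np.maximum(1.0, f) + 1e-9) | (dist <= tol)
    return np.column_stack([u, w]), converged, dist


def metric_scale(surface: NURBSSurface, n: int = 33) -> tuple[float, float]:
    """Mean first-derivative magnitudes (mm per parameter unit) in u and w.

    Multiplying uv coordinates by these scales gives coordinates in which
    distances approximate 3D arc length, so the element size l keeps a
    consistent meaning in the parameter plane.
    """
    (ulo, uhi), (wlo, whi) = surface.domain_u, surface.domain_w
    uu, ww = np.meshgrid(np.linspace(ulo, uhi, n), np.linspace(wlo, whi, n), indexing="ij")
    su, sw = surface.partials(uu.ravel(), ww.ravel())
    return float(np.linalg.norm(su, axis=1).mean()), float(np.linalg.norm(sw, axis=1).mean())


def surface_area(surface: NURBSSurface, polygon_uv: np.ndarray, resolution: int = 200) -> float:
    """3D area of the surface patch over a uv polygon, by dense triangulation."""
    import shapely
    from shapely.geometry import Polygon

    poly = Polygon(polygon_uv)
    minx, miny, maxx, maxy = poly.bounds
    xs = np.linspace(minx, maxx, resolution)
    ys = np.linspace(miny, maxy, resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(poly, grid[:, 0], grid[:, 1])
    pts2 = np.vstack([np.asarray(polygon_uv, dtype=float), grid[inside]])
    tri = _SciDelaunay(pts2)
    cent = pts2[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    sim = tri.simplices[keep]
    xyz = surface.evaluate(pts2[:, 0], pts2[:, 1])
    a, b, c = xyz[sim[:, 0]], xyz[sim[:, 1]], xyz[sim[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
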