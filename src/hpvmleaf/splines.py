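"""B-spline and NURBS primitives used throughout the leaf pipeline.

The curve skeleton of a leaf (margin parts, ridge crests, veins) is carried
by clamped B-spline curves; the auxiliary membrane is a tensor-product
rational (NURBS) surface.  This module provides the basis recursion with the
``0/0 = 0`` convention, least-squares curve fitting with chord-length
parameterization, arc-length machinery, and evaluation of both curves and
surfaces.  Evaluation is vectorised via :class:`scipy.interpolate.BSpline`
design matrices; the explicit Cox–de Boor recursion is kept as the defining
scalar form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = [
    "KnotVector",
    "BSplineCurve",
    "NURBSSurface",
    "bspline_basis",
    "fit_curve",
    "divide_by_arclength",
    "clamped_uniform_knots",
]


@dataclass(frozen=True)
class KnotVector:
    """Non-decreasing sequence of knot values (dimensionless parameters)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("knot vector needs at least two values")
        if np.any(np.diff(vals) < 0):
            raise ValueError("knot vector must be non-decreasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def domain(self, degree: int) -> tuple[float, float]:
        """Evaluable parameter interval for a curve of the given degree."""
        return float(self.values[degree]), float(self.values[-degree - 1])


def clamped_uniform_knots(n_ctrl: int, degree: int, lo: float = 0.0, hi: float = 1.0) -> KnotVector:
    """Open-uniform (clamped) knot vector for ``n_ctrl`` control points."""
    if n_ctrl < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} control points, got {n_ctrl}")
    interior = np.linspace(lo, hi, n_ctrl - degree + 1)[1:-1]
    return KnotVector(np.r_[np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def bspline_basis(i: int, k: int, u: float, knots: KnotVector) -> float:
    """Cox–de Boor basis function N_{i,k}(u).

    Degree 0 is the indicator of the half-open span [u_i, u_{i+1}) (closed at
    the right end of the global domain); any 0/0 term in the recursion is
    taken to be 0.
    """
    t = knots.values
    if not 0 <= i <= len(t) - k - 2:
        raise IndexError(f"basis index {i} out of range for degree {k} and {len(t)} knots")
    if k == 0:
        # close the final span so the domain endpoint is covered
        if t[i] <= u < t[i + 1]:
            return 1.0
        if u == t[i + 1] == t[-1] and t[i] < t[i + 1]:
            return 1.0
        return 0.0
    left_den = t[i + k] - t[i]
    right_den = t[i + k + 1] - t[i + 1]
    left = 0.0 if left_den == 0.0 else (u - t[i]) / left_den * bspline_basis(i, k - 1, u, knots)
    right = (
        0.0
        if right_den == 0.0
        else (t[i + k + 1] - u) / right_den * bspline_basis(i + 1, k - 1, u, knots)
    )
    return left + right


def _basis_matrix(u: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """Dense matrix of all basis functions at the parameters ``u``."""
    u = np.asarray(u, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    uc = np.clip(u, lo, hi)
    return BSpline.design_matrix(uc, knots, degree).toarray()


@dataclass
class BSplineCurve:
    """Clamped B-spline curve in 3D (coordinates in mm)."""

    degree: int
    control_points: np.ndarray
    knots: KnotVector
    fit_rms: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if len(self.control_points) < self.degree + 1:
            raise ValueError("need at least degree+1 control points")
        if len(self.knots) != len(self.control_points) + self.degree + 1:
            raise ValueError("knot count must equal control-point count + degree + 1")

    @property
    def domain(self) -> tuple[float, float]:
        return self.knots.domain(self.degree)

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t) -> np.ndarray:
        """Point(s) on the curve; raises for parameters outside the domain."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.domain
        tol = 1e-12 * max(1.0, abs(hi - lo))
        if np.any(t_arr < lo - tol) or np.any(t_arr > hi + tol):
            raise ValueError(f"parameter outside curve domain [{lo}, {hi}]")
        pts = _basis_matrix(t_arr, self.knots.values, self.degree) @ self.control_points
        return pts[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else pts

    def derivative(self, t) -> np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.domain
        spl = BSpline(self.knots.values, self.control_points, self.degree)
        d = spl.derivative(1)(np.clip(t_arr, lo, hi))
        return d[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else d

    def speed(self, t) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(self.derivative(t)), axis=1)

    # -- arc length -------------------------------------------------------
    _GAUSS_NODES, _GAUSS_WEIGHTS = leggauss(8)
    _N_SEG = 512

    def _cumulative_arclength(self) -> tuple[np.ndarray, np.ndarray]:
        """Composite Gauss–Legendre cumulative arc length on a fine grid."""
        lo, hi = self.domain
        edges = np.linspace(lo, hi, self._N_SEG + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * (edges[1] - edges[0])
        # evaluate speed at all Gauss nodes of all segments at once
        nodes = (mid[:, None] + half * self._GAUSS_NODES[None, :]).ravel()
        sp = self.speed(nodes).reshape(self._N_SEG, -1)
        seg_len = half * (sp * self._GAUSS_WEIGHTS[None, :]).sum(axis=1)
        return edges, np.r_[0.0, np.cumsum(seg_len)]

    def arclength(self) -> float:
        return float(self._cumulative_arclength()[1][-1])

    def param_at_arclength(self, s) -> np.ndarray:
        """Parameters at which cumulative arc length equals ``s`` (monotone inversion)."""
        edges, cum = self._cumulative_arclength()
        s_arr = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
        t = np.interp(s_arr, cum, edges)
        # one Newton step per target refines the piecewise-linear inverse
        for _ in range(3):
            sp = self.speed(t)
            cur = np.interp(t, edges, cum)
            step = np.where(sp > 1e-14, (s_arr - cur) / np.maximum(sp, 1e-14), 0.0)
            t = np.clip(t + step, edges[0], edges[-1])
        return t


def fit_curve(points: np.ndarray, degree: int = 3, smooth: float = 0.0,
              n_ctrl: int | None = None) -> BSplineCurve:
    """Least-squares B-spline fit of an ordered 3D point sequence.

    Chord-length parameterization; the first and last input points are
    interpolated exactly (their control points are pinned).  ``smooth``
    weights a second-difference penalty on the interior control points.
    The RMS residual over the input points is stored on the returned curve
    as ``fit_rms``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] >= 2:
        keep = np.r_[True, np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
        if not keep.all():
            warnings.warn("coincident consecutive points collapsed before fitting", stacklevel=2)
            pts = pts[keep]
    n = len(pts)
    if n < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} distinct points, got {n}")

    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    t = chord / chord[-1] if chord[-1] > 0 else np.linspace(0, 1, n)

    if n_ctrl is None:
        n_ctrl = int(np.clip(n // 2 + 2, degree + 1, min(n, 60)))
    n_ctrl = int(np.clip(n_ctrl, degree + 1, n))
    knots = clamped_uniform_knots(n_ctrl, degree)
    B = _basis_matrix(t, knots.values, degree)

    # pin endpoint control points to the endpoint data points
    p0, pn = pts[0], pts[-1]
    inner = slice(1, n_ctrl - 1)
    rhs = pts - np.outer(B[:, 0], p0) - np.outer(B[:, -1], pn)
    A = B[:, inner]
    if n_ctrl > 3:
        AtA = A.T @ A
        Atb = A.T @ rhs
        if smooth > 0 and n_ctrl - 2 >= 3:
            m = n_ctrl - 2
            D = np.diff(np.eye(m), n=2, axis=0)
            AtA = AtA + smooth * (D.T @ D)
        # mild ridge keeps rank-deficient layouts solvable
        AtA = AtA + 1e-12 * np.trace(AtA) / max(n_ctrl - 2, 1) * np.eye(n_ctrl - 2)
        interior = np.linalg.solve(AtA, Atb)
    else:
        interior = np.empty((n_ctrl - 2, 3))
        if n_ctrl == 3:
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            interior = sol
    ctrl = np.vstack([p0, interior, pn]) if n_ctrl > 2 else np.vstack([p0, pn])
    curve = BSplineCurve(degree=degree, control_points=ctrl, knots=knots)
    resid = curve.evaluate(t) - pts
    curve.fit_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return curve


def divide_by_arclength(curve: BSplineCurve, l: float) -> np.ndarray:
    """Parameters of points equally spaced in arc length, both ends included.

    The spacing is ``L / round(L / l)`` so the final point coincides with the
    curve end; a zero-length (or shorter-than-``l``) curve yields its two end
    parameters (a single parameter when truly degenerate).
    """
    if l <= 0:
        raise ValueError("element size l must be positive")
    L = curve.arclength()
    lo, hi = curve.domain
    if L <= 1e-12:
        return np.array([lo])
    n_seg = max(1, int(round(L / l)))
    s = np.linspace(0.0, L, n_seg + 1)
    t = curve.param_at_arclength(s)
    t[0], t[-1] = lo, hi
    return t


@dataclass
class NURBSSurface:
    """Tensor-product rational B-spline surface p(u, w) (coordinates in mm).

    With all weights equal the surface reduces to the polynomial
    tensor-product B-spline surface over the same control net.  ``degree_w``
    is the degree in the second parameter direction.
    """

    control_net: np.ndarray          # (m+1, n+1, 3)
    weights: np.ndarray              # (m+1, n+1), > 0
    degree_u: int
    degree_w: int
    knots_u: KnotVector
    knots_w: KnotVector

    def __post_init__(self) -> None:
        self.control_net = np.asarray(self.control_net, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.control_net.ndim != 3 or self.control_net.shape[2] != 3:
            raise ValueError("control net must be (m+1, n+1, 3)")
        if self.weights.shape != self.control_net.shape[:2]:
            raise ValueError("weights grid must match the control net")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        mu, nw = self.control_net.shape[:2]
        if len(self.knots_u) != mu + self.degree_u + 1:
            raise ValueError("knots_u inconsistent with control net")
        if len(self.knots_w) != nw + self.degree_w + 1:
            raise ValueError("knots_w inconsistent with control net")

    @property
    def domain_u(self) -> tuple[float, float]:
        return self.knots_u.domain(self.degree_u)

    @property
    def domain_w(self) -> tuple[float, float]:
        return self.knots_w.domain(self.degree_w)

    def _check_domain(self, u: np.ndarray, w: np.ndarray) -> None:
        (ulo, uhi), (wlo, whi) = self.domain_u, self.domain_w
        tol = 1e-12
        if (np.any(u < ulo - tol) or np.any(u > uhi + tol)
                or np.any(w < wlo - tol) or np.any(w > whi + tol)):
            raise ValueError("surface parameter outside domain")

    def evaluate(self, u, w) -> np.ndarray:
        """Rational tensor-product evaluation at paired parameter arrays."""
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        w_arr = np.atleast_1d(np.asarray(w, dtype=float))
        u_arr, w_arr = np.broadcast_arrays(u_arr, w_arr)
        self._check_domain(u_arr, w_arr)
        Bu = _basis_matrix(u_arr.ravel(), self.knots_u.values, self.degree_u)
        Bw = _basis_matrix(w_arr.ravel(), self.knots_w.values, self.degree_w)
        wp = self.weights[..., None] * self.control_net        # (mu, nw, 3)
        num = np.einsum("pi,pj,ijc->pc", Bu, Bw, wp)
        den = np.einsum("pi,pj,ij->p", Bu, Bw, self.weights)
        pts = num / den[:, None]
        scalar = np.isscalar(u) and np.isscalar(w)
        return pts[0] if scalar else pts.reshape(np.shape(u_arr) + (3,))

    def partials(self, u, w, rel_step: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
        """Central-difference partial derivatives (dS/du, dS/dw)."""
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        w_arr = np.atleast_1d(np.asarray(w, dtype=float))
        u_arr, w_arr = np.broadcast_arrays(u_arr, w_arr)
        (ulo, uhi), (wlo, whi) = self.domain_u, self.domain_w
        hu = rel_step * (uhi - ulo)
        hw = rel_step * (whi - wlo)
        u0 = np.clip(u_arr, ulo + hu, uhi - hu)
        w0 = np.clip(w_arr, wlo + hw, whi - hw)
        su = (self.evaluate(u0 + hu, w0) - self.evaluate(u0 - hu, w0)) / (2 * hu)
        sw = (self.evaluate(u0, w0 + hw) - self.evaluate(u0, w0 - hw)) / (2 * hw)
        return su, sw
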