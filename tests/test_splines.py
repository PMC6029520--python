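"""Curve primitives: basis recursion, fitting, arc-length division."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hpvmleaf.splines import (BSplineCurve, KnotVector, bspline_basis,
                              clamped_uniform_knots, divide_by_arclength, fit_curve)

from .oracles import cox_de_boor


def test_degree_zero_basis_is_span_indicator():
    kv = KnotVector(np.arange(8.0))
    assert bspline_basis(2, 0, 2.5, kv) == 1.0
    assert bspline_basis(2, 0, 3.5, kv) == 0.0
    assert bspline_basis(2, 0, 1.0, kv) == 0.0


def test_basis_index_out_of_range():
    kv = clamped_uniform_knots(6, 3)
    with pytest.raises(IndexError, match="99"):
        bspline_basis(99, 3, 0.5, kv)


def test_cubic_basis_matches_independent_recursion():
    kv = KnotVector(np.arange(8.0))
    for i in range(4):
        for u in (3.0, 3.25, 3.5, 3.9):
            assert bspline_basis(i, 3, u, kv) == pytest.approx(
                cox_de_boor(i, 3, u, kv.values), abs=1e-12)


@given(st.integers(1, 3), st.integers(0, 4), st.floats(0.0, 1.0))
def test_partition_of_unity(degree, extra_ctrl, frac):
    n_ctrl = degree + 1 + extra_ctrl
    kv = clamped_uniform_knots(n_ctrl, degree)
    lo, hi = kv.domain(degree)
    u = lo + frac * (hi - lo)
    total = sum(bspline_basis(i, degree, u, kv) for i in range(n_ctrl))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_eval_constant_and_collinear_control_points():
    kv = clamped_uniform_knots(4, 3)
    c1 = BSplineCurve(3, np.tile([1.0, 2.0, 3.0], (4, 1)), kv)
    for t in (0.0, 0.3, 1.0):
        assert np.allclose(c1.evaluate(t), [1, 2, 3])
    line = np.column_stack([np.linspace(0, 9, 4), np.zeros(4), np.zeros(4)])
    c2 = BSplineCurve(3, line, kv)
    p = c2.evaluate(0.37)
    assert abs(p[1]) < 1e-12 and abs(p[2]) < 1e-12 and 0 <= p[0] <= 9


def test_eval_outside_domain_raises():
    kv = clamped_uniform_knots(4, 3)
    c = BSplineCurve(3, np.random.default_rng(0).random((4, 3)), kv)
    with pytest.raises(ValueError, match="domain"):
        c.evaluate(1.5)


def test_eval_matches_scipy_de_boor_oracle():
    rng = np.random.default_rng(3)
    ctrl = rng.random((9, 3)) * 10
    kv = clamped_uniform_knots(9, 3)
    from scipy.interpolate import BSpline
    oracle = BSpline(kv.values, ctrl, 3)
    c = BSplineCurve(3, ctrl, kv)
    for t in (0.0, 0.37, 0.5, 0.93, 1.0):
        assert np.allclose(c.evaluate(t), oracle(t), atol=1e-9)


def test_fit_straight_segment_zero_residual():
    pts = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 5, 20), np.zeros(20)])
    c = fit_curve(pts)
    assert c.fit_rms < 1e-9
    assert np.allclose(c.evaluate(0.0), pts[0], atol=1e-9)
    assert np.allclose(c.evaluate(1.0), pts[-1], atol=1e-9)


def test_fit_endpoints_interpolated():
    rng = np.random.default_rng(1)
    pts = np.cumsum(rng.random((15, 3)), axis=0)
    c = fit_curve(pts)
    lo, hi = c.domain
    assert np.allclose(c.evaluate(lo), pts[0], atol=1e-9)
    assert np.allclose(c.evaluate(hi), pts[-1], atol=1e-9)


def test_fit_quarter_circle_accuracy():
    radius = 20.0
    th = np.linspace(0, np.pi / 2, 40)
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.zeros(40)])
    c = fit_curve(pts, degree=3)
    dense = c.evaluate(np.linspace(0, 1, 500))
    resid = np.abs(np.linalg.norm(dense[:, :2], axis=1) - radius)
    assert resid.max() < 1e-3 * radius


def test_fit_too_few_points_raises():
    with pytest.raises(ValueError, match="degree"):
        fit_curve(np.array([[0.0, 0, 0], [1.0, 0, 0]]), degree=3)


def test_fit_collapses_coincident_points_with_warning():
    pts = np.column_stack([np.r_[0, 1, 1, 2, 3, 4.0], np.zeros(6), np.zeros(6)])
    with pytest.warns(UserWarning, match="coincident"):
        c = fit_curve(pts)
    assert c.fit_rms < 1e-9


def test_divide_straight_segment():
    pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)])
    c = fit_curve(pts)
    t = divide_by_arclength(c, 2.0)
    assert len(t) == 6
    gaps = np.linalg.norm(np.diff(c.evaluate(t), axis=0), axis=1)
    assert np.allclose(gaps, 2.0, atol=1e-6)


def test_divide_l_longer_than_curve_gives_both_ends():
    pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)])
    c = fit_curve(pts)
    t = divide_by_arclength(c, 50.0)
    assert len(t) == 2
    assert t[0] == c.domain[0] and t[-1] == c.domain[1]


def test_divide_quarter_circle_against_polyline_oracle():
    radius = 20.0
    th = np.linspace(0, np.pi / 2, 80)
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.zeros(80)])
    c = fit_curve(pts, degree=3)
    t = divide_by_arclength(c, 5.0)
    assert len(t) == 7  # length 10*pi, spacing 10*pi/6
    # dense polyline oracle for the arc length between consecutive params
    tt = np.linspace(0, 1, 100_001)
    dense = c.evaluate(tt)
    cum = np.r_[0, np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    s = np.interp(t, tt, cum)
    gaps = np.diff(s)
    target = 10 * np.pi / 6
    assert np.all(np.abs(gaps - target) < 1e-3 * target)


def test_divide_spacing_uniform_on_random_cubics():
    rng = np.random.default_rng(11)
    for _ in range(50):
        ctrl = np.cumsum(rng.normal(size=(7, 3)) * 5, axis=0)
        c = BSplineCurve(3, ctrl, clamped_uniform_knots(7, 3))
        t = divide_by_arclength(c, c.arclength() / 9)
        edges, cum = c._cumulative_arclength()
        s = np.interp(t, edges, cum)
        interior = np.diff(s)
        assert interior.std() / interior.mean() < 1e-3


def test_knot_vector_invariants():
    with pytest.raises(ValueError, match="non-decreasing"):
        KnotVector(np.array([0.0, 1.0, 0.5]))
    kv = clamped_uniform_knots(7, 3)
    assert len(kv) == 7 + 3 + 1
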