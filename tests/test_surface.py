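"""NURBS surface evaluation, constrained fitting and inversion."""

import numpy as np
import pytest

from hpvmleaf.hpvm import assemble_hpvm
from hpvmleaf.splines import NURBSSurface, bspline_basis, clamped_uniform_knots
from hpvmleaf.surface import (fit_auxiliary_surface, invert_point, invert_points,
                              metric_scale, surface_area)


def _random_surface(rng, m=5, n=6, rational=True):
    net = np.cumsum(rng.random((m, n, 3)), axis=0) * 10
    w = 1.0 + rng.random((m, n)) if rational else np.ones((m, n))
    return NURBSSurface(control_net=net, weights=w, degree_u=3, degree_w=3,
                        knots_u=clamped_uniform_knots(m, 3),
                        knots_w=clamped_uniform_knots(n, 3))


def _brute_eval(surf, u, w):
    """Direct rational double sum using the scalar basis recursion."""
    m, n = surf.control_net.shape[:2]
    num = np.zeros(3)
    den = 0.0
    for i in range(m):
        bu = bspline_basis(i, surf.degree_u, u, surf.knots_u)
        for j in range(n):
            bw = bspline_basis(j, surf.degree_w, w, surf.knots_w)
            num += bu * bw * surf.weights[i, j] * surf.control_net[i, j]
            den += bu * bw * surf.weights[i, j]
    return num / den


def test_eval_matches_brute_force_double_sum():
    rng = np.random.default_rng(5)
    surf = _random_surface(rng)
    for u, w in rng.random((10, 2)):
        assert np.allclose(surf.evaluate(u, w), _brute_eval(surf, u, w), atol=1e-9)


def test_unit_weights_reduce_to_polynomial_surface():
    rng = np.random.default_rng(6)
    poly = _random_surface(rng, rational=False)
    for u, w in rng.random((100, 2)):
        assert np.allclose(poly.evaluate(u, w), _brute_eval(poly, u, w), atol=1e-9)


def test_bilinear_center_is_corner_average():
    net = np.array([[[0, 0, 0], [0, 1, 2.0]], [[1, 0, 4], [1, 1, 6.0]]])
    surf = NURBSSurface(control_net=net, weights=np.ones((2, 2)), degree_u=1,
                        degree_w=1, knots_u=clamped_uniform_knots(2, 1),
                        knots_w=clamped_uniform_knots(2, 1))
    assert np.allclose(surf.evaluate(0.5, 0.5), net.reshape(4, 3).mean(axis=0))


def test_eval_out_of_domain_raises():
    surf = _random_surface(np.random.default_rng(0))
    with pytest.raises(ValueError, match="domain"):
        surf.evaluate(1.2, 0.5)


def test_weight_positivity_enforced():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="positive"):
        NURBSSurface(control_net=rng.random((4, 4, 3)), weights=np.zeros((4, 4)),
                     degree_u=3, degree_w=3, knots_u=clamped_uniform_knots(4, 3),
                     knots_w=clamped_uniform_knots(4, 3))


def test_planar_model_fits_to_plane(square_sets):
    model = assemble_hpvm(square_sets)
    sfit = fit_auxiliary_surface(model, net_size=(6, 6))
    rng = np.random.default_rng(1)
    uv = 0.05 + 0.9 * rng.random((200, 2))
    z = sfit.surface.evaluate(uv[:, 0], uv[:, 1])[:, 2]
    assert np.abs(z).max() < 1e-6 * 100.0


def test_underdetermined_net_raises(square_sets):
    model = assemble_hpvm(square_sets)
    with pytest.raises(ValueError, match="smaller net"):
        fit_auxiliary_surface(model, net_size=(30, 30))


def test_vein_weight_reduces_vein_residuals(fitted_default, default_leaf):
    model, _ = fitted_default
    low = fit_auxiliary_surface(model, vein_weight=1.0)
    high = fit_auxiliary_surface(model, vein_weight=10.0)

    def vein_resid(sf):
        mask = np.array(["margin" not in cid for cid in sf.constraint_curve_ids])
        return sf.constraint_residuals[mask]

    assert vein_resid(high).mean() <= vein_resid(low).mean() + 1e-12
    assert vein_resid(high).max() <= vein_resid(low).max() + 1e-9


def test_invert_recovers_known_parameters(fitted_default):
    _, sfit = fitted_default
    p = sfit.surface.evaluate(0.3, 0.7)
    q = invert_point(sfit.surface, p)
    assert q.converged
    assert abs(q.u - 0.3) < 1e-6 and abs(q.w - 0.7) < 1e-6


def test_invert_round_trip_on_random_points(fitted_default):
    _, sfit = fitted_default
    rng = np.random.default_rng(9)
    uv0 = 0.05 + 0.9 * rng.random((200, 2))
    pts = sfit.surface.evaluate(uv0[:, 0], uv0[:, 1])
    uv, ok, dist = invert_points(sfit.surface, pts)
    back = sfit.surface.evaluate(uv[:, 0], uv[:, 1])
    err = np.linalg.norm(back - pts, axis=1)
    assert err.max() < 1e-6
    assert ok.all()


def test_invert_normal_displacement_keeps_foot_point(fitted_default):
    _, sfit = fitted_default
    u0, w0 = 0.4, 0.55
    p = sfit.surface.evaluate(u0, w0)
    su, sw = sfit.surface.partials(u0, w0)
    n = np.cross(su[0], sw[0])
    n /= np.linalg.norm(n)
    q = invert_point(sfit.surface, p + 0.05 * n)
    assert abs(q.u - u0) < 1e-4 and abs(q.w - w0) < 1e-4


def test_invert_far_point_flagged_or_clamped(fitted_default):
    _, sfit = fitted_default
    q = invert_point(sfit.surface, np.array([1e4, 1e4, 1e4]))
    on_boundary = min(q.u, q.w, 1 - q.u, 1 - q.w) < 1e-6
    assert (not q.converged) or on_boundary
    assert q.distance > 1.0


def test_metric_scale_matches_planform_extent(fitted_default, default_leaf):
    _, sfit = fitted_default
    su, sw = metric_scale(sfit.surface)
    ext = default_leaf.cloud.max(axis=0) - default_leaf.cloud.min(axis=0)
    # u spans roughly the long planform axis, w the short one (pad ~4%)
    assert 0.7 * max(ext[:2]) < su < 1.6 * max(ext[:2])
    assert 0.7 * min(ext[:2]) < sw < 1.6 * min(ext[:2])


def test_surface_area_recovers_analytic_area(default_leaf, fitted_default):
    _, sfit = fitted_default
    poly3 = np.column_stack([
        default_leaf.planform_polygon,
        default_leaf.height(default_leaf.planform_polygon[:, 0],
                            default_leaf.planform_polygon[:, 1]),
    ])
    uv, _, _ = invert_points(sfit.surface, poly3[::8])
    area = surface_area(sfit.surface, uv, resolution=150)
    assert area == pytest.approx(default_leaf.true_area, rel=0.02)
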