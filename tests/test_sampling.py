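"""Resampling rules: ignore factor, relaxation, advancing front, calibration."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from hpvmleaf.hpvm import FeatureLevel, assemble_hpvm
from hpvmleaf.sampling import (CurveSamples, SamplingConfig, afm_fill,
                               calibrate_points, margin_polygon_uv,
                               min_cross_curve_distance, relax_samples,
                               sample_curves)
from hpvmleaf.surface import fit_auxiliary_surface

from .oracles import brute_nearest


def line_samples(cid, level, start, direction, n, spacing):
    """Straight-line CurveSamples in an identity-scaled uv plane."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s = spacing * np.arange(n)
    uv = start + np.outer(s, d)
    xyz = np.column_stack([uv, np.zeros(n)])
    n_dense = 40 * n
    s_d = np.linspace(0, s[-1], n_dense)
    uv_d = start + np.outer(s_d, d)
    return CurveSamples(curve_id=cid, level=level, params=s.copy(), points_xyz=xyz,
                        points_uv=uv, points_uv_native=uv.copy(), arc_s=s,
                        inversion_ok=np.ones(n, bool), uv_scale=(1.0, 1.0),
                        dense_s=s_d, dense_uv=uv_d,
                        dense_xyz=np.column_stack([uv_d, np.zeros(n_dense)]),
                        dense_uv_native=uv_d.copy())


CFG = SamplingConfig(l=1.0, beta1=0.5, beta2=0.8)


def test_config_invariants():
    with pytest.raises(ValueError, match="beta"):
        SamplingConfig(l=1.0, beta1=0.8, beta2=0.5)
    with pytest.raises(ValueError, match="positive"):
        SamplingConfig(l=0.0)
    with pytest.raises(ValueError, match="alpha"):
        SamplingConfig(l=1.0, alpha=-1.0)


def test_ignore_rule_omits_short_curves(planar_leaf, planar_fitted):
    model, sfit = planar_fitted
    cfg = SamplingConfig(l=30.0, alpha=1.0)
    sampled = {cs.curve_id for cs in sample_curves(model, sfit.surface, cfg)}
    for c in model.curves:
        expect = c.curve.arclength() >= cfg.alpha * cfg.l
        assert (c.id in sampled) == expect, c.id
    # some curve must actually be short enough to be ignored at l=30
    assert sampled != {c.id for c in model.curves}


def test_alpha_zero_samples_everything(planar_leaf, planar_fitted):
    model, sfit = planar_fitted
    cfg = SamplingConfig(l=30.0, alpha=0.0)
    sampled = {cs.curve_id for cs in sample_curves(model, sfit.surface, cfg)}
    assert sampled == {c.id for c in model.curves}


def test_sample_count_for_length_ten_l_two(planar_fitted):
    model, sfit = planar_fitted
    cfg = SamplingConfig(l=2.0)
    for cs in sample_curves(model, sfit.surface, cfg):
        c = model[cs.curve_id]
        L = c.curve.arclength()
        n_expected = max(1, round(L / 2.0)) + 1
        # junction anchors may add at most one point per attached child
        children = sum(1 for ch in model.curves if ch.parent_id == cs.curve_id)
        assert n_expected <= len(cs.params) <= n_expected + children
        assert np.all(np.diff(cs.params) > 0)


def test_relaxation_deletes_below_beta1():
    a = line_samples("a_primary", FeatureLevel.PRIMARY, (-10, 0), (1, 0), 21, 1.0)
    b = line_samples("b_secondary", FeatureLevel.SECONDARY, (-2, 0.4), (1, 0), 5, 1.0)
    fixed = relax_samples([a, b], CFG)
    b_pts = fixed.by_curve("b_secondary")
    # every interior test point sits 0.4 < beta1*l from a fixed point: deleted
    assert len(b_pts) == 2
    assert all(p.is_endpoint for p in b_pts)


def test_relaxation_reinserts_at_midband_arc_distance():
    # nearest fixed point to the test point (0.6, 0) is (0, -0.1): d = 0.608
    a = line_samples("a_primary", FeatureLevel.PRIMARY, (0, -0.1), (1, 0), 16, 2.0)
    b = line_samples("b_secondary", FeatureLevel.SECONDARY, (0.6, -10), (0, 1), 3, 10.0)
    fixed = relax_samples([a, b], CFG)
    b_pts = fixed.by_curve("b_secondary")
    inserted = [p for p in b_pts if not p.is_endpoint]
    assert len(inserted) == 1
    # the blocking point projects onto the curve at y ~ -0.1; the replacement
    # sits (beta1+beta2)/2 * l further along the curve, toward the test point
    assert inserted[0].uv[0] == pytest.approx(0.6, abs=1e-9)
    assert inserted[0].uv[1] == pytest.approx(-0.1 + 0.65, abs=0.1)


def test_relaxation_keeps_isolated_curves():
    a = line_samples("a_primary", FeatureLevel.PRIMARY, (0, 0), (1, 0), 11, 1.0)
    b = line_samples("b_secondary", FeatureLevel.SECONDARY, (0, 100), (1, 0), 11, 1.0)
    fixed = relax_samples([a, b], CFG)
    assert len(fixed.by_curve("b_secondary")) == 11


def test_relaxation_cross_curve_clearance(default_leaf, fitted_default):
    model, sfit = fitted_default
    cfg = SamplingConfig(l=20.0)
    fixed = relax_samples(sample_curves(model, sfit.surface, cfg), cfg)
    assert min_cross_curve_distance(fixed) >= cfg.beta1 * cfg.l - 1e-9


def _square_model_and_surface(side=100.0):
    from .conftest import square_margin_sets

    model = assemble_hpvm(square_margin_sets(side=side, pts_per_side=8))
    sfit = fit_auxiliary_surface(model, net_size=(6, 6))
    return model, sfit


def _hexagon_margin_fixture(l):
    """Closed hexagonal margin front with every edge exactly length l."""
    from types import SimpleNamespace

    from hpvmleaf.sampling import FixedPoint, FixedPointSet

    th = np.pi / 2 + np.linspace(0, 2 * np.pi, 7)[:-1]
    verts = l * np.column_stack([np.cos(th), np.sin(th)])
    pts = [FixedPoint(uv=v.copy(), uv_native=v.copy(),
                      xyz=np.r_[v, 0.0], provenance="margin_0", order=float(k),
                      is_endpoint=k in (0, 5))
           for k, v in enumerate(verts)]
    fixed = FixedPointSet(points=pts, uv_scale=(1.0, 1.0))
    model = SimpleNamespace(margin_part_ids=["margin_0"], curves=[])
    return fixed, model


def test_afm_first_node_is_equilateral_candidate():
    # hexagon of side l: the first front's candidate at height sqrt(3)/2*l
    # is the hexagon centre, farther than r_factor*l from every node, so it
    # is accepted verbatim and forms an exactly equilateral triangle
    cfg = SamplingConfig(l=10.0)
    fixed, model = _hexagon_margin_fixture(cfg.l)
    interior = afm_fill(fixed, model, None, cfg)
    center = np.zeros(2)
    dmin = np.linalg.norm(interior - center, axis=1).min()
    assert dmin < 1e-9
    a, b = fixed.points[0].uv, fixed.points[1].uv
    assert np.linalg.norm(center - a) == pytest.approx(cfg.l, abs=1e-9)
    assert np.linalg.norm(center - b) == pytest.approx(cfg.l, abs=1e-9)


def test_afm_reuses_node_inside_search_radius():
    # second front's candidate lies within r_factor*l of the accepted centre
    # node, so the centre is reused instead of inserting a new node
    cfg = SamplingConfig(l=10.0)
    fixed, model = _hexagon_margin_fixture(cfg.l)
    interior = afm_fill(fixed, model, None, cfg)
    # every other candidate sits sqrt(3)/2*l - apothem ... within r of the
    # centre; the hexagon therefore fills with the centre node alone
    assert len(interior) == 1


def test_afm_nodes_strictly_inside_polygon(planar_fitted):
    model, sfit = planar_fitted
    cfg = SamplingConfig(l=10.0)
    samples = sample_curves(model, sfit.surface, cfg)
    fixed = relax_samples(samples, cfg)
    interior = afm_fill(fixed, model, sfit.surface, cfg)
    loop_pts, _ = margin_polygon_uv(fixed, model)
    poly = Polygon(loop_pts)
    import shapely
    assert shapely.contains_xy(poly, interior[:, 0], interior[:, 1]).all()
    # node reuse keeps interior nodes at least r_factor*l apart
    tree = cKDTree(interior)
    dd, _ = tree.query(interior, k=2)
    assert dd[:, 1].min() >= cfg.r_factor * cfg.l - 1e-9


def test_afm_tiny_polygon_yields_no_interior_points():
    model, sfit = _square_model_and_surface(side=100.0)
    cfg = SamplingConfig(l=150.0, alpha=0.0)
    samples = sample_curves(model, sfit.surface, cfg)
    fixed = relax_samples(samples, cfg)
    interior = afm_fill(fixed, model, sfit.surface, cfg)
    assert len(interior) == 0


def test_calibration_matches_linear_scan_oracle():
    model, sfit = _square_model_and_surface()
    rng = np.random.default_rng(4)
    uv = 0.2 + 0.6 * rng.random((40, 2))
    cloud = sfit.surface.evaluate(*0.2 + 0.6 * rng.random((300, 2)).T) \
        + rng.normal(0, 0.5, (300, 3))
    cfg = SamplingConfig(l=10.0)
    out = calibrate_points(uv, sfit.surface, cloud, cfg)
    lifted = sfit.surface.evaluate(uv[:, 0], uv[:, 1])
    for k in range(len(uv)):
        j = brute_nearest(cloud, lifted[k])
        if np.linalg.norm(cloud[j] - lifted[k]) <= cfg.snap_max * cfg.l:
            assert np.allclose(out[k], cloud[j])
        else:
            assert np.allclose(out[k], lifted[k])


def test_calibration_without_cloud_lifts_only():
    model, sfit = _square_model_and_surface()
    uv = np.array([[0.5, 0.5], [0.3, 0.6]])
    out = calibrate_points(uv, sfit.surface, None, SamplingConfig(l=10.0))
    assert np.allclose(out, sfit.surface.evaluate(uv[:, 0], uv[:, 1]))


def test_calibration_respects_snap_cap():
    model, sfit = _square_model_and_surface()
    uv = np.array([[0.5, 0.5]])
    lifted = sfit.surface.evaluate(uv[:, 0], uv[:, 1])
    cfg = SamplingConfig(l=10.0)
    far_cloud = lifted + np.array([[0, 0, 2 * cfg.snap_max * cfg.l]])
    out = calibrate_points(uv, sfit.surface, far_cloud, cfg)
    assert np.allclose(out, lifted)
    near_cloud = lifted + np.array([[0, 0, 0.4 * cfg.snap_max * cfg.l]])
    out2 = calibrate_points(uv, sfit.surface, near_cloud, cfg)
    assert np.allclose(out2, near_cloud)


def test_sampling_is_deterministic(planar_fitted):
    model, sfit = planar_fitted
    cfg = SamplingConfig(l=15.0, seed=7)

    def run():
        fixed = relax_samples(sample_curves(model, sfit.surface, cfg), cfg)
        interior = afm_fill(fixed, model, sfit.surface, cfg)
        return fixed.uv_array(), interior

    a1, i1 = run()
    a2, i2 = run()
    assert a1.tobytes() == a2.tobytes()
    assert i1.tobytes() == i2.tobytes()
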