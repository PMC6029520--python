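"""PSLG construction, constrained Delaunay triangulation, smoothing."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from hpvmleaf._delaunay import constrained_delaunay, delaunay_triangles
from hpvmleaf.meshing import (PSLG, TriMesh, cdt, lift_and_optimize,
                              resolve_duplicate_u)
from hpvmleaf.sampling import INTERIOR
from hpvmleaf.splines import NURBSSurface, clamped_uniform_knots

from .oracles import brute_delaunay_edges, random_pslg


def _edges_of(tris):
    out = set()
    for a, b, c in tris:
        out |= {tuple(sorted(e)) for e in ((a, b), (b, c), (c, a))}
    return out


def test_square_with_constrained_diagonal():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
    tris = constrained_delaunay(pts, [(0, 2)])
    assert len(tris) == 2
    assert (0, 2) in _edges_of(tris)


def test_delaunay_matches_bruteforce_on_small_sets():
    rng = np.random.default_rng(12)
    for _ in range(20):
        pts = rng.random((25, 2))
        oracle = brute_delaunay_edges(pts)
        if oracle is None:
            continue
        assert _edges_of(delaunay_triangles(pts)) == oracle


def test_constraints_retained_on_random_pslgs():
    rng = np.random.default_rng(21)
    for _ in range(5):
        pts, cons = random_pslg(rng, n=40, k=8)
        es = _edges_of(constrained_delaunay(pts, cons))
        assert all(tuple(sorted(c)) in es for c in cons)


def test_collinear_input_raises():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        delaunay_triangles(pts)


def test_duplicate_points_raise():
    pts = np.array([[0, 0], [1, 1], [1, 1], [0, 1.0]])
    with pytest.raises(ValueError, match="duplicate"):
        delaunay_triangles(pts)


def test_resolve_duplicate_u_identity_when_unique():
    pslg = PSLG(vertices=np.array([[0, 0], [1, 1], [2, 0.0]]),
                constrained_edges=[], margin_loop=[], provenance=["a"] * 3)
    out = resolve_duplicate_u(pslg, seed=0)
    assert np.array_equal(out.vertices, pslg.vertices)


def test_resolve_duplicate_u_perturbs_minimally():
    pslg = PSLG(vertices=np.array([[1.0, 0], [1.0, 5], [2.0, 1]]),
                constrained_edges=[], margin_loop=[], provenance=["a"] * 3)
    eps = 1e-6
    out = resolve_duplicate_u(pslg, eps=eps, seed=3)
    assert len(np.unique(out.vertices[:, 0])) == 3
    moved = np.abs(out.vertices[:, 0] - pslg.vertices[:, 0])
    assert (moved > 0).sum() == 1
    assert moved.max() < eps


def test_resolve_duplicate_u_grid():
    gx, gy = np.meshgrid(np.arange(5.0), np.arange(5.0))
    pslg = PSLG(vertices=np.column_stack([gx.ravel(), gy.ravel()]),
                constrained_edges=[], margin_loop=[], provenance=["a"] * 25)
    eps = 1e-5
    out = resolve_duplicate_u(pslg, eps=eps, seed=1)
    assert len(np.unique(out.vertices[:, 0])) == 25
    assert np.abs(out.vertices[:, 0] - pslg.vertices[:, 0]).max() < eps


def test_crossing_constraints_rejected(default_leaf, fitted_default, remesh20):
    # inject two crossing vein polylines directly at the PSLG level
    v = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0], [2, 2], [3, 3]])
    from hpvmleaf.meshing import _segments_properly_cross
    assert _segments_properly_cross(v, (0, 1), (2, 3))
    assert not _segments_properly_cross(v, (0, 1), (4, 5))


def test_mesh_partitions_margin_polygon(remesh20):
    mesh = remesh20.mesh
    poly = Polygon(mesh.vertices_uv[mesh.margin_loop])
    assert mesh.uv_areas().sum() == pytest.approx(poly.area, rel=1e-6)
    assert (mesh.uv_areas() > 0).all()


def test_euler_relation_for_triangulated_polygon(remesh20):
    mesh = remesh20.mesh
    used = np.unique(mesh.triangles)
    V = len(used)
    E = len(mesh.edge_set())
    F = mesh.n_triangles
    assert V - E + F == 1


def test_constrained_edges_present_in_leaf_mesh(remesh20):
    mesh = remesh20.mesh
    assert mesh.constrained_edges <= mesh.edge_set()


def _planar_surface():
    net = np.zeros((2, 2, 3))
    net[:, :, 0] = [[0, 0], [1, 1]]
    net[:, :, 1] = [[0, 1], [0, 1]]
    return NURBSSurface(control_net=net, weights=np.ones((2, 2)), degree_u=1,
                        degree_w=1, knots_u=clamped_uniform_knots(2, 1),
                        knots_w=clamped_uniform_knots(2, 1))


def _hex_patch(center=(0.5, 0.5), r=0.3, center_off=(0.1, 0.05)):
    th = np.linspace(0, 2 * np.pi, 7)[:-1]
    ring = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    verts = np.vstack([[center[0] + center_off[0], center[1] + center_off[1]], ring])
    tris = np.array([[0, 1 + k, 1 + (k + 1) % 6] for k in range(6)])
    xyz = np.column_stack([verts, np.zeros(len(verts))])
    return TriMesh(vertices_uv=verts, vertices_xyz=xyz, triangles=tris,
                   provenance=[INTERIOR] + ["margin_0"] * 6)


def test_smoothing_zero_iters_is_identity():
    mesh = _hex_patch()
    before = mesh.vertices_uv.copy()
    out = lift_and_optimize(mesh, _planar_surface(), iters=0)
    assert np.array_equal(out.vertices_uv, before)


def test_smoothing_fixed_when_all_constrained():
    mesh = _hex_patch()
    mesh.provenance = ["margin_0"] * 7
    before = mesh.vertices_uv.copy()
    out = lift_and_optimize(mesh, _planar_surface(), iters=25)
    assert np.array_equal(out.vertices_uv, before)


def test_smoothing_moves_interior_vertex_to_neighbor_centroid():
    mesh = _hex_patch()
    out = lift_and_optimize(mesh, _planar_surface(), iters=50)
    centroid = out.vertices_uv[1:].mean(axis=0)
    assert np.linalg.norm(out.vertices_uv[0] - centroid) < 1e-3
    # no inverted triangles
    assert (out.uv_areas() > 0).all()


def test_cdt_from_pslg_flags_constrained_edges():
    rng = np.random.default_rng(8)
    pts, cons = random_pslg(rng, n=30, k=6)
    pslg = PSLG(vertices=pts, constrained_edges=[tuple(sorted(c)) for c in cons],
                margin_loop=[], provenance=["x"] * len(pts))
    mesh = cdt(resolve_duplicate_u(pslg, seed=0))
    assert mesh.constrained_edges <= mesh.edge_set()
    assert (mesh.uv_areas() > 0).all()
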