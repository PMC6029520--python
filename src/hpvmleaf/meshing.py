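"""Constrained Delaunay meshing of the sampled leaf and post-optimization.

The sampled points live in metric-scaled uv; consecutive samples of each
skeleton curve become constrained edges (the discrete HPVM), the closed
margin loop bounds the domain, and interior advancing-front points are free
vertices.  After triangulation, triangles whose centroid falls outside the
margin polygon are culled, vertices are lifted to 3D, and unconstrained
interior vertices are relaxed by Laplacian smoothing in uv with triangle
inversions rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from ._delaunay import constrained_delaunay
from .hpvm import HPVMModel
from .sampling import INTERIOR, FixedPointSet, margin_polygon_uv
from .splines import NURBSSurface

__all__ = ["PSLG", "TriMesh", "build_pslg", "resolve_duplicate_u", "cdt",
           "cull_outside", "lift_and_optimize"]


@dataclass
class PSLG:
    """Planar straight-line graph in metric-scaled uv."""

    vertices: np.ndarray                       # (N, 2)
    constrained_edges: list[tuple[int, int]]
    margin_loop: list[int]                     # ordered CCW vertex indices
    provenance: list[str]
    xyz: np.ndarray | None = None              # (N, 3) known positions
    uv_scale: tuple[float, float] = (1.0, 1.0)

    @property
    def bounding_rectangle(self) -> tuple[float, float, float, float]:
        return (float(self.vertices[:, 0].min()), float(self.vertices[:, 1].min()),
                float(self.vertices[:, 0].max()), float(self.vertices[:, 1].max()))


@dataclass
class TriMesh:
    """Triangulation with paired uv (metric-scaled) and xyz coordinates."""

    vertices_uv: np.ndarray
    vertices_xyz: np.ndarray
    triangles: np.ndarray                      # (M, 3) CCW in uv
    constrained_edges: set[tuple[int, int]] = field(default_factory=set)
    provenance: list[str] = field(default_factory=list)
    margin_loop: list[int] = field(default_factory=list)
    uv_scale: tuple[float, float] = (1.0, 1.0)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices_uv)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_set(self) -> set[tuple[int, int]]:
        e: set[tuple[int, int]] = set()
        for a, b, c in self.triangles:
            e.add(tuple(sorted((int(a), int(b)))))
            e.add(tuple(sorted((int(b), int(c)))))
            e.add(tuple(sorted((int(c), int(a)))))
        return e

    def uv_areas(self) -> np.ndarray:
        p = self.vertices_uv
        a, b, c = (p[self.triangles[:, k]] for k in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0]))

    def xyz_areas(self) -> np.ndarray:
        p = self.vertices_xyz
        a, b, c = (p[self.triangles[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _segments_properly_cross(p: np.ndarray, e1: tuple[int, int], e2: tuple[int, int]) -> bool:
    a, b = p[e1[0]], p[e1[1]]
    c, d = p[e2[0]], p[e2[1]]

    def o(u, v, w):
        return (v[0] - u[0]) * (w[1] - u[1]) - (v[1] - u[1]) * (w[0] - u[0])

    # near-collinear contacts (junction vertices on a chord) are not crossings
    tol = 1e-9 * max(np.linalg.norm(b - a) * np.linalg.norm(d - c), 1e-300)

    def sgn(x):
        return 0.0 if abs(x) <= tol else x

    return (sgn(o(a, b, c)) * sgn(o(a, b, d)) < 0) and \
        (sgn(o(c, d, a)) * sgn(o(c, d, b)) < 0)


def build_pslg(fixed: FixedPointSet, interior: np.ndarray, model: HPVMModel,
               interior_xyz: np.ndarray | None = None,
               weld_tol: float | None = None) -> PSLG:
    """Vertices plus constrained skeleton edges, interior points free.

    Coincident curve endpoints (margin part joints, vein junctions landing on
    a parent sample) are welded into single vertices.  Crossing constrained
    edges raise a ValueError naming the offending pair.
    """
    uv_all = fixed.uv_array()
    if weld_tol is None:
        diag = np.linalg.norm(uv_all.max(axis=0) - uv_all.min(axis=0)) if len(uv_all) else 1.0
        weld_tol = 1e-7 * max(diag, 1e-12)

    verts: list[np.ndarray] = []
    xyz: list[np.ndarray] = []
    prov: list[str] = []
    fp_index: dict[int, int] = {}
    tree_pts: list[np.ndarray] = []
    for k, fp in enumerate(fixed.points):
        vid = None
        if fp.is_endpoint and verts:
            arr = np.asarray(tree_pts)
            d = np.linalg.norm(arr - fp.uv, axis=1)
            j = int(np.argmin(d))
            if d[j] <= weld_tol:
                vid = j
        if vid is None:
            vid = len(verts)
            verts.append(fp.uv.astype(float))
            xyz.append(fp.xyz.astype(float))
            prov.append(fp.provenance)
            tree_pts.append(fp.uv.astype(float))
        fp_index[k] = vid

    edges: set[tuple[int, int]] = set()
    id_of = {id(p): i for i, p in enumerate(fixed.points)}
    for c in model.curves:
        part = fixed.by_curve(c.id)
        for p, q in zip(part, part[1:]):
            a, b = fp_index[id_of[id(p)]], fp_index[id_of[id(q)]]
            if a != b:
                edges.add((min(a, b), max(a, b)))
    # close the margin loop
    _, loop_fp = margin_polygon_uv(fixed, model)
    loop = []
    for i in loop_fp:
        v = fp_index[i]
        if not loop or loop[-1] != v:
            loop.append(v)
    if len(loop) > 1 and loop[0] == loop[-1]:
        loop.pop()
    for a, b in zip(loop, loop[1:] + loop[:1]):
        if a != b:
            edges.add((min(a, b), max(a, b)))

    interior = np.atleast_2d(np.asarray(interior, dtype=float)) if len(interior) else \
        np.empty((0, 2))
    for k, p in enumerate(interior):
        verts.append(p)
        xyz.append(interior_xyz[k] if interior_xyz is not None else np.full(3, np.nan))
        prov.append(INTERIOR)

    v_arr = np.asarray(verts)
    edge_list = sorted(edges)
    for i, e1 in enumerate(edge_list):
        for e2 in edge_list[i + 1:]:
            if set(e1) & set(e2):
                continue
            if _segments_properly_cross(v_arr, e1, e2):
                raise ValueError(f"constrained edges {e1} and {e2} cross; "
                                 "upstream relaxation left conflicting samples")
    return PSLG(vertices=v_arr, constrained_edges=edge_list, margin_loop=loop,
                provenance=prov, xyz=np.asarray(xyz), uv_scale=fixed.uv_scale)


def resolve_duplicate_u(pslg: PSLG, eps: float | None = None, seed: int = 0) -> PSLG:
    """Perturb u-coordinates until all are unique (|du| < eps, seeded).

    The strip divide-and-conquer requires one vertex per vertical strip; the
    deterministic resample keeps the constrained topology unchanged.
    """
    v = pslg.vertices.copy()
    if eps is None:
        span = max(v[:, 0].max() - v[:, 0].min(), 1e-12) if len(v) else 1.0
        eps = 1e-9 * span
    rng = np.random.default_rng(seed)
    orig = v[:, 0].copy()
    for _ in range(100):
        _, first = np.unique(v[:, 0], return_index=True)
        dup = np.setdiff1d(np.arange(len(v)), first)
        if len(dup) == 0:
            break
        v[dup, 0] = orig[dup] + (rng.random(len(dup)) * 1.9 - 0.95) * eps
    else:
        raise RuntimeError("could not make u-coordinates unique")
    return PSLG(vertices=v, constrained_edges=pslg.constrained_edges,
                margin_loop=pslg.margin_loop, provenance=pslg.provenance,
                xyz=pslg.xyz, uv_scale=pslg.uv_scale)


def cdt(pslg: PSLG) -> TriMesh:
    """Constrained Delaunay triangulation of the PSLG (uv only).

    All constrained edges appear in the output; every other edge is locally
    Delaunay with respect to visible vertices.
    """
    tris = constrained_delaunay(pslg.vertices, pslg.constrained_edges)
    mesh = TriMesh(vertices_uv=pslg.vertices.copy(),
                   vertices_xyz=pslg.xyz.copy() if pslg.xyz is not None
                   else np.full((len(pslg.vertices), 3), np.nan),
                   triangles=np.asarray(tris, dtype=int),
                   constrained_edges={(min(a, b), max(a, b))
                                      for a, b in pslg.constrained_edges},
                   provenance=list(pslg.provenance),
                   margin_loop=list(pslg.margin_loop),
                   uv_scale=pslg.uv_scale)
    missing = mesh.constrained_edges - mesh.edge_set()
    if missing:
        raise RuntimeError(f"constrained edges lost in triangulation: {sorted(missing)}")
    return mesh


def cull_outside(mesh: TriMesh, polygon: np.ndarray | None = None) -> TriMesh:
    """Drop triangles whose uv centroid lies outside the margin polygon."""
    if polygon is None:
        polygon = mesh.vertices_uv[mesh.margin_loop]
    poly = Polygon(polygon)
    cent = mesh.vertices_uv[mesh.triangles].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    mesh.triangles = mesh.triangles[keep]
    return mesh


def lift_and_optimize(mesh: TriMesh, surface: NURBSSurface,
                      cloud: np.ndarray | None = None, iters: int = 10,
                      snap_dist: float | None = None) -> TriMesh:
    """Lift vertices to 3D and Laplacian-smooth free interior vertices.

    Vertices with curve provenance (and hence all boundary vertices) are
    immovable; a move that would invert any incident uv triangle is
    rejected.  Moved vertices are re-lifted through the surface after every
    round and re-snapped to the cloud (within ``snap_dist``) at the end.
    """
    scale = np.asarray(mesh.uv_scale, dtype=float)
    missing = ~np.isfinite(mesh.vertices_xyz).all(axis=1)
    if missing.any():
        nat = mesh.vertices_uv[missing] / scale
        mesh.vertices_xyz[missing] = surface.evaluate(nat[:, 0], nat[:, 1])
    if iters <= 0 or mesh.n_triangles == 0:
        return mesh

    movable = np.array([p == INTERIOR for p in mesh.provenance], dtype=bool)
    if not movable.any():
        return mesh
    nbrs: dict[int, set[int]] = {}
    incident: dict[int, list[tuple[int, int]]] = {}
    for a, b, c in mesh.triangles:
        a, b, c = int(a), int(b), int(c)
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            nbrs.setdefault(u, set()).update((v, w))
            incident.setdefault(u, []).append((v, w))

    uv = mesh.vertices_uv
    moved = np.zeros(mesh.n_vertices, dtype=bool)
    order = [i for i in range(mesh.n_vertices) if movable[i] and i in nbrs]
    for _ in range(iters):
        for i in order:
            target = uv[list(nbrs[i])].mean(axis=0)
            ok = True
            for v, w in incident[i]:
                d = ((uv[v, 0] - target[0]) * (uv[w, 1] - target[1])
                     - (uv[v, 1] - target[1]) * (uv[w, 0] - target[0]))
                if d <= 0:
                    ok = False
                    break
            if ok:
                uv[i] = target
                moved[i] = True
        if moved.any():
            nat = uv[moved] / scale
            mesh.vertices_xyz[moved] = surface.evaluate(nat[:, 0], nat[:, 1])
    if cloud is not None and len(cloud) and snap_dist is not None and moved.any():
        tree = cKDTree(np.asarray(cloud, dtype=float))
        d, idx = tree.query(mesh.vertices_xyz[moved])
        snap = d <= snap_dist
        rows = np.where(moved)[0][snap]
        mesh.vertices_xyz[rows] = np.asarray(cloud)[idx[snap]]
    return mesh
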