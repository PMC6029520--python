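"""Mesh quality and approximation-error metrics.

Four numbers summarise a remeshing run: the element (triangle) count, the
percentage of triangles passing a minimum-interior-angle criterion, the
relative error of the total 3D mesh area against a reference area, and the
maximum distance from the scanned cloud to the mesh (cloud-to-mesh,
point-to-nearest-triangle, computed exactly).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .meshing import TriMesh

__all__ = ["QualityReport", "percentage_of_pass", "area_error",
           "max_distance_error", "min_angles_deg", "quality_report"]


@dataclass
class QualityReport:
    size: float                   # element size l used (mm)
    element_number: int
    percentage_of_pass: float     # %
    area_error: float             # % relative to the reference area
    max_distance_error: float     # mm

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def table(reports: list["QualityReport"]) -> str:
        head = (f"{'Size (mm)':>10} {'Element number':>15} {'Percentage of pass [%]':>23} "
                f"{'Area error [%]':>15} {'Maximum distance error (mm)':>28}")
        rows = [head]
        for r in reports:
            rows.append(f"{r.size:>10.4g} {r.element_number:>15d} "
                        f"{r.percentage_of_pass:>23.2f} {r.area_error:>15.2f} "
                        f"{r.max_distance_error:>28.4f}")
        return "\n".join(rows)


def min_angles_deg(mesh: TriMesh) -> np.ndarray:
    """Minimum interior angle of every triangle, from the 3D coordinates."""
    p = mesh.vertices_xyz
    tri = mesh.triangles
    a, b, c = p[tri[:, 0]], p[tri[:, 1]], p[tri[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)

    def ang(opp, s1, s2):
        cosv = (s1**2 + s2**2 - opp**2) / np.maximum(2 * s1 * s2, 1e-300)
        return np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))

    return np.minimum.reduce([ang(la, lb, lc), ang(lb, la, lc), ang(lc, la, lb)])


def percentage_of_pass(mesh: TriMesh, min_angle: float = 30.0) -> float:
    """% of triangles whose minimum interior angle reaches ``min_angle``."""
    if mesh.n_triangles == 0:
        raise ValueError("empty mesh")
    return float(100.0 * np.mean(min_angles_deg(mesh) >= min_angle))


def area_error(mesh: TriMesh, reference_area: float) -> float:
    """100 * |sum of 3D triangle areas - reference| / reference (%)."""
    if reference_area <= 0:
        raise ValueError("reference_area must be positive")
    return float(100.0 * abs(mesh.xyz_areas().sum() - reference_area) / reference_area)


def _point_triangle_dist_block(P: np.ndarray, A: np.ndarray, B: np.ndarray,
                               C: np.ndarray) -> np.ndarray:
    """Exact distances, points (N,3) x triangles (M,3): returns (N, M)."""
    ab = B - A
    ac = C - A
    bc = C - B
    Pk = P[:, None, :]
    ap = Pk - A[None]
    bp = Pk - B[None]
    cp = Pk - C[None]
    d1 = np.einsum("mk,nmk->nm", ab, ap)
    d2 = np.einsum("mk,nmk->nm", ac, ap)
    d3 = np.einsum("mk,nmk->nm", ab, bp)
    d4 = np.einsum("mk,nmk->nm", ac, bp)
    d5 = np.einsum("mk,nmk->nm", ab, cp)
    d6 = np.einsum("mk,nmk->nm", ac, cp)

    with np.errstate(divide="ignore", invalid="ignore"):
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        # interior projection
        denom = va + vb + vc
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        close = A[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        # edge AB
        t_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0),
                       0.0, 1.0)
        close_ab = A[None] + t_ab[..., None] * ab[None]
        # edge AC
        t_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0),
                       0.0, 1.0)
        close_ac = A[None] + t_ac[..., None] * ac[None]
        # edge BC
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.clip(np.where(den_bc != 0, num_bc / np.where(den_bc != 0, den_bc, 1.0), 0.0),
                       0.0, 1.0)
        close_bc = B[None] + t_bc[..., None] * bc[None]

    res = close.copy()
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    res = np.where(m_bc[..., None], close_bc, res)
    res = np.where(m_ac[..., None], close_ac, res)
    res = np.where(m_ab[..., None], close_ab, res)
    res = np.where(m_c[..., None], np.broadcast_to(C[None], res.shape), res)
    res = np.where(m_b[..., None], np.broadcast_to(B[None], res.shape), res)
    res = np.where(m_a[..., None], np.broadcast_to(A[None], res.shape), res)
    return np.linalg.norm(res - Pk, axis=2)


def cloud_to_mesh_distances(cloud: np.ndarray, mesh: TriMesh,
                            chunk: int = 256) -> np.ndarray:
    """Distance from every cloud point to its nearest mesh triangle (exact)."""
    P = np.atleast_2d(np.asarray(cloud, dtype=float))
    tri = mesh.triangles
    V = mesh.vertices_xyz
    best = np.full(len(P), np.inf)
    for k in range(0, len(tri), chunk):
        sl = tri[k:k + chunk]
        d = _point_triangle_dist_block(P, V[sl[:, 0]], V[sl[:, 1]], V[sl[:, 2]])
        best = np.minimum(best, d.min(axis=1))
    return best


def max_distance_error(mesh: TriMesh, cloud: np.ndarray) -> float:
    """Maximum cloud-to-mesh distance in mm."""
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    if len(cloud) == 0:
        raise ValueError("cloud must be non-empty")
    return float(cloud_to_mesh_distances(cloud, mesh).max())


def quality_report(mesh: TriMesh, size: float, reference_area: float,
                   cloud: np.ndarray | None = None,
                   min_angle: float = 30.0) -> QualityReport:
    return QualityReport(
        size=float(size),
        element_number=int(mesh.n_triangles),
        percentage_of_pass=percentage_of_pass(mesh, min_angle=min_angle),
        area_error=area_error(mesh, reference_area),
        max_distance_error=(max_distance_error(mesh, cloud)
                            if cloud is not None and len(cloud) else 0.0),
    )
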