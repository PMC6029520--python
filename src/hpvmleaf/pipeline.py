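"""End-to-end orchestration: features -> skeleton -> surface -> mesh -> report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hpvm import FeaturePointSet, HPVMModel, assemble_hpvm, validate_hpvm
from .meshing import TriMesh, build_pslg, cdt, cull_outside, lift_and_optimize, resolve_duplicate_u
from .quality import QualityReport, quality_report
from .sampling import (FixedPointSet, SamplingConfig, afm_fill, calibrate_points,
                       relax_samples, sample_curves)
from .surface import SurfaceFit, fit_auxiliary_surface
from .synthetic import SyntheticLeaf

__all__ = ["RemeshResult", "fit_leaf", "remesh", "run_suite"]


@dataclass
class RemeshResult:
    mesh: TriMesh
    fixed: FixedPointSet
    interior_uv: np.ndarray
    interior_xyz: np.ndarray
    cfg: SamplingConfig


def fit_leaf(sets: list[FeaturePointSet], tol: float | None = None,
             net_size: tuple[int, int] = (15, 15), vein_weight: float = 2.0,
             smoothing: float = 1e-2) -> tuple[HPVMModel, SurfaceFit]:
    """Assemble and validate the skeleton, then fit the auxiliary surface."""
    model = assemble_hpvm(sets, tol=tol)
    report = validate_hpvm(model)
    if not report.valid:
        raise ValueError(f"invalid skeleton: {report.violations}")
    sfit = fit_auxiliary_surface(model, net_size=net_size, vein_weight=vein_weight,
                                 smoothing=smoothing)
    return model, sfit


def remesh(model: HPVMModel, sfit: SurfaceFit, cloud: np.ndarray | None,
           cfg: SamplingConfig, iters: int = 10) -> RemeshResult:
    """Multi-step resampling and constrained Delaunay meshing at one size."""
    surface = sfit.surface
    samples = sample_curves(model, surface, cfg)
    fixed = relax_samples(samples, cfg)
    interior = afm_fill(fixed, model, surface, cfg)
    interior_xyz = calibrate_points(interior, surface, cloud, cfg,
                                    uv_scale=fixed.uv_scale)
    pslg = build_pslg(fixed, interior, model, interior_xyz=interior_xyz,
                      weld_tol=0.05 * cfg.l)
    pslg = resolve_duplicate_u(pslg, seed=cfg.seed)
    mesh = cdt(pslg)
    mesh = cull_outside(mesh)
    mesh = lift_and_optimize(mesh, surface, cloud=cloud, iters=iters,
                             snap_dist=cfg.snap_max * cfg.l)
    return RemeshResult(mesh=mesh, fixed=fixed, interior_uv=interior,
                        interior_xyz=interior_xyz, cfg=cfg)


def run_suite(leaf: SyntheticLeaf, sizes: list[float], iters: int = 10,
              min_angle: float = 30.0, seed: int | None = None,
              **cfg_kwargs) -> tuple[list[QualityReport], list[RemeshResult]]:
    """Remesh one leaf at several element sizes and report quality metrics."""
    model, sfit = fit_leaf(leaf.truth_sets)
    reports: list[QualityReport] = []
    results: list[RemeshResult] = []
    for size in sizes:
        cfg = SamplingConfig(l=float(size),
                             seed=seed if seed is not None else leaf.params.seed,
                             **cfg_kwargs)
        res = remesh(model, sfit, leaf.cloud, cfg, iters=iters)
        reports.append(quality_report(res.mesh, size=float(size),
                                      reference_area=leaf.true_area,
                                      cloud=leaf.cloud, min_angle=min_angle))
        results.append(res)
    return reports, results
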