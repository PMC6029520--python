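"""Hierarchical parametric vein-and-margin (HPVM) skeleton of a leaf.

A leaf skeleton is a level-coded set of B-spline curves: the closed margin
loop (split at sharp points into parts), optional ridge-crest lines
expressing wrinkles, and a vein hierarchy in which primary veins attach to
the margin, secondary veins to primary (or other secondary) veins and
tertiary veins to secondary veins.  Assembly fits one curve per coded
feature point set, working from low levels to high, and resolves each vein's
parent by projecting its start point onto admissible lower-level curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.optimize import minimize_scalar

from .splines import BSplineCurve, fit_curve

__all__ = [
    "FeatureLevel",
    "FeaturePointSet",
    "HPVMCurve",
    "HPVMModel",
    "ValidationReport",
    "assemble_hpvm",
    "validate_hpvm",
    "closest_point_on_curve",
]


class FeatureLevel(IntEnum):
    """Low-to-high feature hierarchy of the leaf blade."""

    MARGIN = 0
    RIDGE = 1
    PRIMARY = 2
    SECONDARY = 3
    TERTIARY = 4


#: admissible parent levels for each level; margin and ridge curves are free
PARENT_LEVELS: dict[FeatureLevel, tuple[FeatureLevel, ...]] = {
    FeatureLevel.MARGIN: (),
    FeatureLevel.RIDGE: (),
    FeatureLevel.PRIMARY: (FeatureLevel.MARGIN,),
    FeatureLevel.SECONDARY: (FeatureLevel.PRIMARY, FeatureLevel.SECONDARY),
    FeatureLevel.TERTIARY: (FeatureLevel.SECONDARY,),
}

ROLES = {"start", "end", "branch", "junction", "sharp", "none"}


@dataclass
class FeaturePointSet:
    """Ordered, level-coded feature points for one curve (mm)."""

    level: FeatureLevel
    points: np.ndarray
    roles: list[str] | None = None
    parent_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 2:
            raise ValueError("a feature point set needs at least 2 points")
        if self.roles is None:
            self.roles = ["start"] + ["none"] * (len(self.points) - 2) + ["end"]
        if len(self.roles) != len(self.points):
            raise ValueError("roles must align with points")
        unknown = set(self.roles) - ROLES
        if unknown:
            raise ValueError(f"unknown roles {sorted(unknown)}")


@dataclass
class HPVMCurve:
    id: str
    curve: BSplineCurve
    level: FeatureLevel
    parent_id: str | None = None
    attach_param: float | None = None


@dataclass
class ValidationReport:
    closure_gap: float
    attach_residuals: dict[str, float]
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


@dataclass
class HPVMModel:
    curves: list[HPVMCurve]
    margin_part_ids: list[str]
    junctions: list[tuple[np.ndarray, list[str]]] = field(default_factory=list)
    tol: float = 0.0

    def __getitem__(self, cid: str) -> HPVMCurve:
        for c in self.curves:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def by_level(self, level: FeatureLevel) -> list[HPVMCurve]:
        return [c for c in self.curves if c.level == level]

    def margin_loop_points(self, per_part: int = 64) -> np.ndarray:
        """Dense ordered polyline of the closed margin loop."""
        pts = []
        for cid in self.margin_part_ids:
            c = self[cid].curve
            lo, hi = c.domain
            pts.append(c.evaluate(np.linspace(lo, hi, per_part))[:-1])
        return np.vstack(pts)

    def bbox_diagonal(self) -> float:
        pts = np.vstack([c.curve.control_points for c in self.curves])
        return float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))


def closest_point_on_curve(curve: BSplineCurve, p: np.ndarray,
                           n_seed: int = 200) -> tuple[float, float]:
    """(parameter, distance) of the closest point of ``curve`` to ``p``."""
    lo, hi = curve.domain
    ts = np.linspace(lo, hi, n_seed)
    d = np.linalg.norm(curve.evaluate(ts) - p, axis=1)
    i = int(np.argmin(d))
    a, b = ts[max(i - 1, 0)], ts[min(i + 1, n_seed - 1)]
    if b > a:
        res = minimize_scalar(lambda t: float(np.linalg.norm(curve.evaluate(t) - p)),
                              bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10 * max(1.0, hi - lo)})
        if res.fun <= d[i]:
            return float(res.x), float(res.fun)
    return float(ts[i]), float(d[i])


def _default_tol(sets: list[FeaturePointSet]) -> float:
    margin_pts = np.vstack([s.points for s in sets if s.level == FeatureLevel.MARGIN])
    return 0.01 * float(np.linalg.norm(margin_pts.max(axis=0) - margin_pts.min(axis=0)))


def _order_margin_parts(parts: list[tuple[str, BSplineCurve]], tol: float) -> list[str]:
    """Chain margin parts head-to-tail into one loop by endpoint proximity."""
    if len(parts) == 1:
        return [parts[0][0]]
    remaining = dict(parts)
    order = [parts[0][0]]
    cur_end = parts[0][1].evaluate(parts[0][1].domain[1])
    del remaining[parts[0][0]]
    while remaining:
        best = min(
            remaining.items(),
            key=lambda kv: np.linalg.norm(kv[1].evaluate(kv[1].domain[0]) - cur_end),
        )
        cid, curve = best
        order.append(cid)
        cur_end = curve.evaluate(curve.domain[1])
        del remaining[cid]
    return order


def assemble_hpvm(sets: list[FeaturePointSet], tol: float | None = None,
                  degree: int = 3, smooth: float = 0.0) -> HPVMModel:
    """Fit curves per feature set (low level first) and resolve attachments.

    Parents are resolved per set: an explicit ``parent_id`` is honoured,
    otherwise the admissible lower-level curve nearest to the set's start
    point is taken.  A start point farther than ``tol`` from every
    admissible parent raises a ``ValueError`` naming the set.
    """
    if not any(s.level == FeatureLevel.MARGIN for s in sets):
        raise ValueError("at least one MARGIN feature set is required")
    if tol is None:
        tol = _default_tol(sets)

    counters: dict[FeatureLevel, int] = {}
    labelled: list[tuple[str, FeaturePointSet]] = []
    for s in sets:
        k = counters.get(s.level, 0)
        counters[s.level] = k + 1
        labelled.append((f"{s.level.name.lower()}_{k}", s))

    curves: list[HPVMCurve] = []
    junctions: list[tuple[np.ndarray, list[str]]] = []
    for level in sorted(FeatureLevel):
        for cid, s in labelled:
            if s.level != level:
                continue
            bs = fit_curve(s.points, degree=degree, smooth=smooth)
            hc = HPVMCurve(id=cid, curve=bs, level=level)
            admissible_levels = PARENT_LEVELS[level]
            if admissible_levels:
                candidates = [c for c in curves if c.level in admissible_levels]
                if s.parent_id is not None:
                    candidates = [c for c in candidates if c.id == s.parent_id]
                start = bs.evaluate(bs.domain[0])
                best: tuple[float, float, str] | None = None
                for cand in candidates:
                    t, d = closest_point_on_curve(cand.curve, start)
                    if best is None or d < best[0]:
                        best = (d, t, cand.id)
                if best is None or best[0] > tol:
                    raise ValueError(
                        f"unresolved parent for set {cid!r}: start point farther than "
                        f"tol={tol:.4g} mm from every admissible parent curve"
                    )
                hc.parent_id = best[2]
                hc.attach_param = best[1]
                junctions.append((start.copy(), [best[2], cid]))
            curves.append(hc)

    margin = [(c.id, c.curve) for c in curves if c.level == FeatureLevel.MARGIN]
    margin_ids = _order_margin_parts(margin, tol)
    for a, b in zip(margin_ids, margin_ids[1:] + margin_ids[:1]):
        ca, cb = next(c for i, c in margin if i == a), next(c for i, c in margin if i == b)
        junctions.append((ca.evaluate(ca.domain[1]).copy(), [a, b]))
    return HPVMModel(curves=curves, margin_part_ids=margin_ids, junctions=junctions, tol=tol)


def validate_hpvm(model: HPVMModel, tol: float | None = None) -> ValidationReport:
    """Report margin closure, attachment residuals and level-rule violations."""
    if tol is None:
        tol = model.tol or 0.01 * model.bbox_diagonal()
    violations: list[str] = []

    gaps = []
    ids = model.margin_part_ids
    for a, b in zip(ids, ids[1:] + ids[:1]):
        ca, cb = model[a].curve, model[b].curve
        gaps.append(float(np.linalg.norm(ca.evaluate(ca.domain[1]) - cb.evaluate(cb.domain[0]))))
    closure_gap = max(gaps) if gaps else 0.0
    if closure_gap > tol:
        violations.append(f"margin loop not closed: max gap {closure_gap:.4g} mm > tol")

    attach: dict[str, float] = {}
    for c in model.curves:
        allowed = PARENT_LEVELS[c.level]
        if not allowed:
            if c.parent_id is not None:
                violations.append(f"{c.id}: level {c.level.name} must not have a parent")
            continue
        if c.parent_id is None:
            violations.append(f"{c.id}: missing parent")
            continue
        parent = model[c.parent_id]
        if parent.level not in allowed:
            violations.append(
                f"{c.id}: parent level {parent.level.name} violates the attachment rule"
            )
        start = c.curve.evaluate(c.curve.domain[0])
        t = c.attach_param
        if t is None:
            t, _ = closest_point_on_curve(parent.curve, start)
        lo, hi = parent.curve.domain
        t = float(np.clip(t, lo, hi))
        r = float(np.linalg.norm(parent.curve.evaluate(t) - start))
        attach[c.id] = r
        if r > tol:
            violations.append(f"{c.id}: attach residual {r:.4g} mm > tol")
    return ValidationReport(closure_gap=closure_gap, attach_residuals=attach,
                            violations=violations)
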