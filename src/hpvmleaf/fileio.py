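"""File formats: PLY/OBJ geometry, the HPVM feature JSON, YAML run configs.

All coordinates are millimetres.  Clouds and meshes round-trip through
trimesh; two small writers live here because trimesh does not support them:
ASCII PLY point clouds carrying an integer provenance scalar per vertex, and
OBJ files with uv texture coordinates plus ``l`` line elements marking
constrained skeleton edges.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .hpvm import FeatureLevel, FeaturePointSet, HPVMModel
from .meshing import TriMesh

__all__ = [
    "read_cloud", "write_cloud", "read_mesh", "write_mesh_obj",
    "read_hpvm_json", "write_hpvm_json", "RunConfig", "load_run_config",
]


# ---------------------------------------------------------------------------
# point clouds and meshes
# ---------------------------------------------------------------------------

def read_cloud(path: str | Path) -> np.ndarray:
    """(N, 3) coordinates from a PLY/OBJ file; normals and colors ignored."""
    path = Path(path)
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if isinstance(obj, trimesh.points.PointCloud):
        v = np.asarray(obj.vertices, dtype=float)
    elif hasattr(obj, "vertices"):
        v = np.asarray(obj.vertices, dtype=float)
    else:
        raise ValueError(f"{path} contains no vertex data")
    if v.size == 0:
        raise ValueError(f"{path} contains no vertices")
    return v


def write_cloud(path: str | Path, points: np.ndarray,
                provenance: np.ndarray | None = None) -> None:
    """ASCII PLY point cloud, optionally with an integer provenance scalar."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lines = ["ply", "format ascii 1.0", "comment units mm",
             f"element vertex {len(points)}",
             "property double x", "property double y", "property double z"]
    if provenance is not None:
        lines.append("property int provenance")
    lines.append("end_header")
    for i, p in enumerate(points):
        row = f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
        if provenance is not None:
            row += f" {int(provenance[i])}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path) -> TriMesh:
    """Triangle mesh from PLY/OBJ (xyz only; uv taken from the file if present)."""
    path = Path(path)
    try:
        m = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if not hasattr(m, "faces") or len(m.faces) == 0:
        raise ValueError(f"{path} contains no triangles")
    v = np.asarray(m.vertices, dtype=float)
    uv = None
    if m.visual is not None and getattr(m.visual, "uv", None) is not None:
        uv = np.asarray(m.visual.uv, dtype=float)
    if uv is None or len(uv) != len(v):
        uv = v[:, :2].copy()
    return TriMesh(vertices_uv=uv, vertices_xyz=v,
                   triangles=np.asarray(m.faces, dtype=int),
                   provenance=["UNKNOWN"] * len(v))


def write_mesh_obj(path: str | Path, mesh: TriMesh) -> None:
    """OBJ with vertices, uv texture coordinates, faces and constrained
    edges as ``l`` line elements; deterministic formatting."""
    lines = ["# units mm"]
    for p in mesh.vertices_xyz:
        lines.append(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    for q in mesh.vertices_uv:
        lines.append(f"vt {q[0]:.9g} {q[1]:.9g}")
    for a, b, c in mesh.triangles:
        lines.append(f"f {a + 1}/{a + 1} {b + 1}/{b + 1} {c + 1}/{c + 1}")
    for a, b in sorted(mesh.constrained_edges):
        lines.append(f"l {a + 1} {b + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# HPVM feature JSON
# ---------------------------------------------------------------------------

class _SetSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    level: str
    points: list[list[float]]
    roles: list[str] | None = None
    parent_id: str | None = None

    @field_validator("level")
    @classmethod
    def _known_level(cls, v: str) -> str:
        if v not in FeatureLevel.__members__:
            raise ValueError(f"unknown feature level {v!r}")
        return v

    @field_validator("points")
    @classmethod
    def _xyz(cls, v: list[list[float]]) -> list[list[float]]:
        if any(len(p) != 3 for p in v):
            raise ValueError("points must be [x, y, z] triples")
        return v


class _CurveSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    level: str
    degree: int
    knots: list[float]
    control_points: list[list[float]]
    parent_id: str | None = None
    attach_param: float | None = None


class _FileSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    units: str
    sets: list[_SetSchema]
    curves: list[_CurveSchema] | None = None


def read_hpvm_json(path: str | Path) -> list[FeaturePointSet]:
    """Validated feature point sets from the HPVM JSON format."""
    raw = json.loads(Path(path).read_text())
    try:
        data = _FileSchema.model_validate(raw)
    except Exception as exc:
        raise ValueError(f"invalid HPVM file {path}: {exc}") from exc
    if data.units != "mm":
        raise ValueError(f"unsupported units {data.units!r}; only mm")
    out = []
    for i, s in enumerate(data.sets):
        try:
            out.append(FeaturePointSet(level=FeatureLevel[s.level],
                                       points=np.asarray(s.points, dtype=float),
                                       roles=s.roles, parent_id=s.parent_id))
        except ValueError as exc:
            raise ValueError(f"set {i}: {exc}") from exc
    return out


def write_hpvm_json(obj: HPVMModel | list[FeaturePointSet], path: str | Path) -> None:
    """Serialize feature sets, or a fitted model (curves included)."""
    if isinstance(obj, HPVMModel):
        payload = {
            "units": "mm",
            "sets": [],
            "curves": [
                {
                    "id": c.id,
                    "level": c.level.name,
                    "degree": c.curve.degree,
                    "knots": [float(k) for k in c.curve.knots.values],
                    "control_points": [[float(x) for x in p]
                                       for p in c.curve.control_points],
                    "parent_id": c.parent_id,
                    "attach_param": None if c.attach_param is None
                    else float(c.attach_param),
                }
                for c in obj.curves
            ],
        }
    else:
        payload = {
            "units": "mm",
            "sets": [
                {
                    "level": s.level.name,
                    "points": [[float(x) for x in p] for p in s.points],
                    "roles": list(s.roles),
                    "parent_id": s.parent_id,
                }
                for s in obj
            ],
        }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    features: str
    cloud: str | None = None
    size: float = 10.0
    alpha: float = 1.0
    beta1: float = 0.5
    beta2: float = 0.8
    iters: int = 10
    seed: int = 0
    vein_weight: float = 2.0
    net: int = 15
    out_dir: str = "."
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate(yaml.safe_load(Path(path).read_text()))
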