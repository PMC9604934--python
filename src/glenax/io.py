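"""Readers and writers for labeled meshes, landmark files and result tables.

Meshes travel as PLY (preferred; region labels embedded as a ``uchar
region`` vertex property), or as STL/OBJ with a sidecar CSV
(``vertex_index,label``) since those formats carry no attributes.  Meshes
are always loaded with ``process=False`` so vertex order — and hence label
alignment — is preserved.

Landmarks travel as JSON (one object per rater) or long-format CSV with
columns ``rater_id,landmark,x,y,z`` where the landmark names are
``trigonum``, ``glenoid_upper_apex``, ``glenoid_lower_apex``,
``inferior_angle`` and ``fossa_1`` .. ``fossa_5``.

All coordinates are millimetres; no unit autodetection is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import trimesh

from .errors import ValidationError
from .types import CODE_REGIONS, REGION_CODES, LandmarkSet, ScapulaMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
]

_MESH_SUFFIXES = {".ply", ".stl", ".obj"}
_FOSSA_NAMES = [f"fossa_{i}" for i in range(1, 6)]
_POINT_NAMES = ["trigonum", "glenoid_upper_apex", "glenoid_lower_apex", "inferior_angle"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.csv")


def _labels_from_ply(mesh: trimesh.Trimesh) -> Optional[np.ndarray]:
    raw = mesh.metadata.get("_ply_raw", {})
    vdata = raw.get("vertex", {}).get("data", {})
    if "region" not in vdata:
        return None
    codes = np.asarray(vdata["region"]).ravel().astype(int)
    unknown = sorted(set(codes.tolist()) - set(CODE_REGIONS))
    if unknown:
        raise ValidationError(f"PLY 'region' property contains unknown codes: {unknown}")
    return np.array([CODE_REGIONS[c] for c in codes])


def _labels_from_csv(path: Path, n_vertices: int) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"vertex_index", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"label sidecar {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    labels = np.full(n_vertices, "", dtype=object)
    idx = df["vertex_index"].to_numpy(dtype=int)
    if idx.min() < 0 or idx.max() >= n_vertices:
        raise ValidationError(
            f"label sidecar indexes vertices outside [0, {n_vertices - 1}]"
        )
    labels[idx] = df["label"].astype(str).to_numpy()
    if np.any(labels == ""):
        missing = int((labels == "").sum())
        raise ValidationError(f"label sidecar leaves {missing} vertices unlabeled")
    return labels.astype(str)


def read_mesh(
    path: Union[str, Path],
    label_source: Optional[Union[str, Path]] = None,
    laterality: str = "right",
) -> ScapulaMesh:
    """Load a labeled scapula mesh.

    Labels come from the PLY ``region`` vertex property when present,
    otherwise from ``label_source`` (a ``vertex_index,label`` CSV; defaults
    to ``<path>.labels.csv`` next to the mesh).  Laterality is not stored in
    mesh formats and must be supplied by the caller (default right).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"mesh file not found: {path}")
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValidationError(
            f"unsupported mesh format {path.suffix!r}; expected one of {sorted(_MESH_SUFFIXES)}"
        )
    mesh = trimesh.load(path, process=False, force="mesh")
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    labels = None
    if path.suffix.lower() == ".ply" and label_source is None:
        labels = _labels_from_ply(mesh)
    if labels is None:
        sidecar = Path(label_source) if label_source is not None else _sidecar_path(path)
        if not sidecar.exists():
            raise ValidationError(
                f"no labels found for {path}: neither an embedded PLY 'region' "
                f"property nor a sidecar file {sidecar}"
            )
        labels = _labels_from_csv(sidecar, len(vertices))
    return ScapulaMesh(vertices=vertices, faces=faces, labels=labels, laterality=laterality)


def write_mesh(mesh: ScapulaMesh, path: Union[str, Path]) -> Path:
    """Write a labeled mesh.

    PLY embeds the labels as a ``uchar region`` vertex property (ASCII
    encoding, so the file stays text); STL and OBJ get a
    ``<path>.labels.csv`` sidecar.  Returns the mesh path.

    Note PLY stores coordinates as 32-bit floats; round-trips are exact for
    float32-representable coordinates.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _MESH_SUFFIXES:
        raise ValidationError(f"unsupported mesh format {suffix!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if suffix == ".ply":
        codes = np.array([REGION_CODES[lab] for lab in mesh.labels], dtype=np.uint8)
        tm.vertex_attributes["region"] = codes
        tm.export(path, encoding="ascii")
    else:
        tm.export(path)
        if suffix == ".stl":
            # STL is a triangle soup: the file stores 3 vertices per facet in
            # face order, so the sidecar must label that ordering
            labels = mesh.labels[mesh.faces.ravel()]
        else:
            labels = mesh.labels
        df = pd.DataFrame({"vertex_index": np.arange(len(labels)), "label": labels})
        df.to_csv(_sidecar_path(path), index=False)
    return path


def _landmarks_from_json(path: Path) -> LandmarkSet:
    with open(path) as fh:
        data = json.load(fh)
    required = set(_POINT_NAMES) | {"fossa_points"}
    missing = sorted(required - set(data))
    if missing:
        raise ValidationError(f"landmark file {path} is missing fields: {missing}")
    fossa = np.asarray(data["fossa_points"], dtype=float)
    if fossa.shape != (5, 3):
        raise ValidationError(
            f"fossa_points must have 5 entries of 3 coordinates, got shape {fossa.shape}"
        )
    return LandmarkSet(
        trigonum=data["trigonum"],
        glenoid_upper_apex=data["glenoid_upper_apex"],
        glenoid_lower_apex=data["glenoid_lower_apex"],
        fossa_points=fossa,
        inferior_angle=data["inferior_angle"],
        rater_id=data.get("rater_id", "unknown"),
    )


def _landmarks_from_csv(path: Path) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"landmark CSV {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    points = {}
    for _, row in df.iterrows():
        points[str(row["landmark"])] = [row["x"], row["y"], row["z"]]
    missing = sorted((set(_POINT_NAMES) | set(_FOSSA_NAMES)) - set(points))
    if missing:
        raise ValidationError(f"landmark CSV {path} is missing rows: {missing}")
    n_fossa = sum(1 for k in points if k.startswith("fossa_"))
    if n_fossa != 5:
        raise ValidationError(f"fossa_points must have 5 entries, got {n_fossa}")
    rater = str(df["rater_id"].iloc[0]) if "rater_id" in df.columns else "unknown"
    return LandmarkSet(
        trigonum=points["trigonum"],
        glenoid_upper_apex=points["glenoid_upper_apex"],
        glenoid_lower_apex=points["glenoid_lower_apex"],
        fossa_points=[points[n] for n in _FOSSA_NAMES],
        inferior_angle=points["inferior_angle"],
        rater_id=rater,
    )


def read_landmarks(path: Union[str, Path]) -> LandmarkSet:
    """Load one rater's landmark set from JSON or long-format CSV."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".json":
        return _landmarks_from_json(path)
    if path.suffix.lower() == ".csv":
        return _landmarks_from_csv(path)
    raise ValidationError(f"unsupported landmark format {path.suffix!r} (use .json or .csv)")


def write_landmarks(lms: LandmarkSet, path: Union[str, Path]) -> Path:
    """Write a landmark set as JSON or long-format CSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "rater_id": lms.rater_id,
            "trigonum": lms.trigonum.tolist(),
            "glenoid_upper_apex": lms.glenoid_upper_apex.tolist(),
            "glenoid_lower_apex": lms.glenoid_lower_apex.tolist(),
            "fossa_points": lms.fossa_points.tolist(),
            "inferior_angle": lms.inferior_angle.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path
    if path.suffix.lower() == ".csv":
        rows = []
        named = [
            ("trigonum", lms.trigonum),
            ("glenoid_upper_apex", lms.glenoid_upper_apex),
            ("glenoid_lower_apex", lms.glenoid_lower_apex),
            ("inferior_angle", lms.inferior_angle),
        ] + [(n, p) for n, p in zip(_FOSSA_NAMES, lms.fossa_points)]
        for name, p in named:
            rows.append({"rater_id": lms.rater_id, "landmark": name,
                         "x": p[0], "y": p[1], "z": p[2]})
        pd.DataFrame(rows).to_csv(path, index=False)
        return path
    raise ValidationError(f"unsupported landmark format {path.suffix!r} (use .json or .csv)")
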