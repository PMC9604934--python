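"""Core domain types.

The pipeline works entirely on the *output* of a CT segmentation: a triangle
surface of the scapula whose vertices carry anatomical region labels, plus
per-rater landmark picks.  All coordinates are millimetres; angles are
degrees in the public API.

Geometric primitives (:class:`Plane`, :class:`Axis`, :class:`Sphere`) are
anatomy-agnostic; anatomical orientation conventions live in
:class:`MeasurementFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import ValidationError

#: Recognised per-vertex anatomical regions.
REGIONS = ("body", "spine", "glenoid", "acromion", "coracoid", "fossa")

#: Regions that must be non-empty for a mesh to be measurable.
MANDATORY_REGIONS = ("body", "spine", "glenoid")

#: Integer codes used when labels are stored as a PLY vertex property.
REGION_CODES: Dict[str, int] = {name: i for i, name in enumerate(REGIONS)}
CODE_REGIONS: Dict[int, str] = {i: name for name, i in REGION_CODES.items()}

LATERALITIES = ("left", "right")

#: Transverse-axis construction tags.
METHODS = ("y_axis", "gt_line", "bflf")

_UNIT_TOL = 1e-9


def _as_point(x, name: str) -> np.ndarray:
    p = np.asarray(x, dtype=float).reshape(-1)
    if p.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    if not np.all(np.isfinite(p)):
        raise ValidationError(f"{name} contains non-finite coordinates")
    return p


def _as_unit(x, name: str) -> np.ndarray:
    v = _as_point(x, name)
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > 1e-6:
        raise ValidationError(f"{name} must be a unit vector (norm {n:.3g})")
    # renormalize to machine precision so downstream invariants hold exactly
    return v / n


@dataclass
class Plane:
    """A plane given by an anchor point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = _as_point(self.point, "Plane.point")
        self.normal = _as_unit(self.normal, "Plane.normal")

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal


@dataclass
class Axis:
    """A line given by an anchor point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.point = _as_point(self.point, "Axis.point")
        self.direction = _as_unit(self.direction, "Axis.direction")

    def reversed(self) -> "Axis":
        return Axis(self.point.copy(), -self.direction)


@dataclass
class Sphere:
    """A sphere given by its center and radius (mm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = _as_point(self.center, "Sphere.center")
        self.radius = float(self.radius)
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValidationError(f"Sphere.radius must be > 0, got {self.radius}")


@dataclass
class ScapulaMesh:
    """A labeled triangle surface standing in for the segmented scapula.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    labels : (n,) array of region names, one per vertex, each in
        :data:`REGIONS`
    laterality : "left" or "right"; defaults to "right".  Left scapulae are
        handled by the sign conventions of the measurement frame, never by
        mirroring the data.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray
    laterality: str = "right"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise ValidationError(f"vertices must be (n, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("vertices contain non-finite coordinates")
        f = np.asarray(self.faces, dtype=np.int64)
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValidationError(
                f"face indices must lie in [0, {len(v) - 1}]; "
                f"found range [{f.min()}, {f.max()}]"
            )
        lab = np.asarray(self.labels)
        if lab.shape != (len(v),):
            raise ValidationError(
                f"labels must be one per vertex ({len(v)}), got shape {lab.shape}"
            )
        lab = lab.astype(str)
        unknown = sorted(set(lab.tolist()) - set(REGIONS))
        if unknown:
            raise ValidationError(f"unknown region labels: {unknown}")
        for region in MANDATORY_REGIONS:
            if not np.any(lab == region):
                raise ValidationError(
                    f"mesh has no vertex labeled '{region}' "
                    f"(mandatory regions: {MANDATORY_REGIONS})"
                )
        if self.laterality not in LATERALITIES:
            raise ValidationError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        self.vertices, self.faces, self.labels = v, f, lab

    def region_mask(self, *regions: str) -> np.ndarray:
        for r in regions:
            if r not in REGIONS:
                raise ValidationError(f"unknown region {r!r}")
        return np.isin(self.labels, regions)

    def region_vertices(self, *regions: str) -> np.ndarray:
        return self.vertices[self.region_mask(*regions)]


@dataclass
class LandmarkSet:
    """One rater's picked anatomical points on a scapula model.

    ``fossa_points`` are the five picks placed regularly along the bottom of
    the supraspinatus fossa; ``trigonum`` is the intersection of the scapular
    spine with the medial border; the glenoid apexes bound the superoinferior
    extent of the glenoid rim; ``inferior_angle`` is the inferior tip of the
    scapular blade (used only to orient the superior direction).
    """

    trigonum: np.ndarray
    glenoid_upper_apex: np.ndarray
    glenoid_lower_apex: np.ndarray
    fossa_points: np.ndarray
    inferior_angle: np.ndarray
    rater_id: str = "unknown"

    def __post_init__(self):
        self.trigonum = _as_point(self.trigonum, "trigonum")
        self.glenoid_upper_apex = _as_point(self.glenoid_upper_apex, "glenoid_upper_apex")
        self.glenoid_lower_apex = _as_point(self.glenoid_lower_apex, "glenoid_lower_apex")
        self.inferior_angle = _as_point(self.inferior_angle, "inferior_angle")
        fp = np.asarray(self.fossa_points, dtype=float)
        if fp.shape != (5, 3):
            raise ValidationError(
                f"fossa_points must have 5 entries of 3 coordinates, got shape {fp.shape}"
            )
        if not np.all(np.isfinite(fp)):
            raise ValidationError("fossa_points contain non-finite coordinates")
        if np.linalg.norm(self.glenoid_upper_apex - self.glenoid_lower_apex) < 1e-9:
            raise ValidationError("glenoid upper and lower apex must be distinct")
        self.fossa_points = fp
        self.rater_id = str(self.rater_id)


@dataclass
class MeasurementFrame:
    """Anatomical orientation conventions used to sign the inclination.

    ``frontal_plane.normal`` points anteriorly (given laterality);
    ``lateral_dir`` and ``superior_dir`` form an orthonormal in-plane pair.
    A glenoid facing superiorly then yields a positive inclination on either
    side of the body.
    """

    frontal_plane: Plane
    superior_dir: np.ndarray
    lateral_dir: np.ndarray

    def __post_init__(self):
        self.superior_dir = _as_unit(self.superior_dir, "superior_dir")
        self.lateral_dir = _as_unit(self.lateral_dir, "lateral_dir")
        n = self.frontal_plane.normal
        for name, v in (("superior_dir", self.superior_dir), ("lateral_dir", self.lateral_dir)):
            if abs(float(v @ n)) > _UNIT_TOL * 10:
                raise ValidationError(f"{name} must lie in the frontal plane")
        if abs(float(self.superior_dir @ self.lateral_dir)) > _UNIT_TOL * 10:
            raise ValidationError("superior_dir and lateral_dir must be orthogonal")


@dataclass
class InclinationResult:
    """Signed glenoid inclination plus the constructions that produced it."""

    method: str
    inclination_deg: float
    transverse_axis: Axis
    glenoid_axis: Axis
    frontal_plane: Plane
    frame: Optional[MeasurementFrame] = field(default=None, repr=False)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        self.inclination_deg = float(self.inclination_deg)
        if not (-90.0 < self.inclination_deg < 90.0):
            raise ValidationError(
                f"inclination must lie in (-90, 90) degrees, got {self.inclination_deg}"
            )
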