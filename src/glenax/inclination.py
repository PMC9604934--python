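"""Glenoid inclination measurement.

The measurement needs three constructions on a labeled scapula surface:

1. the **scapular frontal plane** — the mean plane of every vertex except
   the glenoid, acromion and coracoid;
2. a **transverse axis** — one of three constructions:

   * ``y_axis``: best-fit line to all vertices at the spine/body boundary,
     translated through the glenoid center (fully automatic);
   * ``gt_line``: line through the glenoid center and the picked trigonum;
   * ``bflf``: best-fit line to the five supraspinatus-fossa picks
     (Best-Fit Line Fossa);

3. the **glenoid mediolateral axis** — from the glenoid center (midpoint of
   the picked upper/lower glenoid apexes) toward the center of the best-fit
   sphere of the glenoid surface.

Both axes are projected onto the frontal plane and the signed angle between
the projections is the glenoid inclination, positive when the glenoid faces
superiorly.  The sign convention is made explicit by a
:class:`~glenax.types.MeasurementFrame` (the superior reference runs from
the inferior angle to the glenoid center) and is laterality-invariant.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError
from .fitting import fit_line, fit_plane, fit_sphere, project_direction, signed_angle
from .types import (
    Axis,
    InclinationResult,
    LandmarkSet,
    MeasurementFrame,
    Plane,
    ScapulaMesh,
    Sphere,
)

__all__ = [
    "frontal_plane",
    "spine_body_intersection_points",
    "y_axis",
    "glenoid_center",
    "gt_line",
    "bflf_axis",
    "glenoid_axis",
    "measurement_frame",
    "inclination",
    "measure_inclination",
]

#: Regions entering the frontal-plane fit: everything except glenoid,
#: acromion and coracoid.
FRONTAL_REGIONS = ("body", "spine", "fossa")


def _orient(direction: np.ndarray, hint: np.ndarray) -> np.ndarray:
    """Flip ``direction`` so it has a positive component along ``hint``."""
    return -direction if float(direction @ hint) < 0 else direction


def _anterior_hint(mesh: ScapulaMesh) -> np.ndarray:
    """Coarse anterior direction inferred from region centroids.

    Lateral ~ body centroid -> glenoid centroid; superior ~ body centroid ->
    spine(+fossa) centroid (the spine borders the supraspinatus fossa and
    sits superior to the bulk of the blade).  Anterior completes a
    right-handed anatomical triad whose handedness depends on laterality.
    """
    body_c = mesh.region_vertices("body").mean(axis=0)
    lat = mesh.region_vertices("glenoid").mean(axis=0) - body_c
    sup_regions = ("spine", "fossa") if mesh.region_mask("fossa").any() else ("spine",)
    sup = mesh.region_vertices(*sup_regions).mean(axis=0) - body_c
    if mesh.laterality == "right":
        hint = np.cross(sup, lat)
    else:
        hint = np.cross(lat, sup)
    n = float(np.linalg.norm(hint))
    if n < 1e-9:
        raise DegenerateGeometryError(
            "cannot infer anterior direction: region centroids are collinear"
        )
    return hint / n


def frontal_plane(mesh: ScapulaMesh) -> Plane:
    """Mean plane of the scapula excluding glenoid, acromion and coracoid,
    with the normal oriented anteriorly for the mesh's laterality."""
    pts = mesh.region_vertices(*FRONTAL_REGIONS)
    plane = fit_plane(pts)
    normal = _orient(plane.normal, _anterior_hint(mesh))
    return Plane(point=plane.point, normal=normal)


def spine_body_intersection_points(mesh: ScapulaMesh) -> np.ndarray:
    """Vertices on the spine/body boundary, in ascending vertex order.

    A vertex is on the boundary iff it shares a mesh edge with a vertex of
    the other label (so the boundary strip contains vertices of both
    regions).
    """
    labels = mesh.labels
    f = mesh.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    la, lb = labels[edges[:, 0]], labels[edges[:, 1]]
    cross_edge = ((la == "spine") & (lb == "body")) | ((la == "body") & (lb == "spine"))
    idx = np.unique(edges[cross_edge])
    if idx.size == 0:
        raise DegenerateGeometryError(
            "spine and body regions do not touch: no shared edge found"
        )
    return mesh.vertices[idx]


def y_axis(
    mesh: ScapulaMesh,
    glenoid_center: np.ndarray,
    boundary_line: Optional[Axis] = None,
) -> Axis:
    """Transverse axis from the spine/body boundary (fully automatic).

    Best-fit line to the boundary vertices, re-anchored at the glenoid
    center and oriented laterally.  ``boundary_line`` may pass a
    pre-computed fit (used by the study pipeline to avoid refitting per
    rater); it never depends on any landmark file.
    """
    gc = np.asarray(glenoid_center, dtype=float).reshape(3)
    if boundary_line is None:
        pts = spine_body_intersection_points(mesh)
        boundary_line = fit_line(pts)
    direction = _orient(boundary_line.direction, gc - boundary_line.point)
    return Axis(point=gc, direction=direction)


def glenoid_center(landmarks: LandmarkSet) -> np.ndarray:
    """Center of the segment between the upper and lower glenoid apex."""
    return 0.5 * (landmarks.glenoid_upper_apex + landmarks.glenoid_lower_apex)


def gt_line(glenoid_center: np.ndarray, trigonum: np.ndarray) -> Axis:
    """Glenoid-Trigonum line, anchored at the glenoid center and pointing
    laterally (from trigonum toward glenoid)."""
    gc = np.asarray(glenoid_center, dtype=float).reshape(3)
    tri = np.asarray(trigonum, dtype=float).reshape(3)
    d = gc - tri
    n = float(np.linalg.norm(d))
    if n < 1e-9:
        raise DegenerateGeometryError("gt_line: glenoid center and trigonum coincide")
    return Axis(point=gc, direction=d / n)


def bflf_axis(landmarks: LandmarkSet, glenoid_center: np.ndarray) -> Axis:
    """Best-Fit Line Fossa: best-fit line to the five fossa picks, anchored
    at the glenoid center and oriented laterally (toward the glenoid)."""
    gc = np.asarray(glenoid_center, dtype=float).reshape(3)
    line = fit_line(landmarks.fossa_points)
    direction = _orient(line.direction, gc - line.point)
    return Axis(point=gc, direction=direction)


def glenoid_axis(
    mesh: ScapulaMesh,
    glenoid_center: np.ndarray,
    sphere: Optional[Sphere] = None,
) -> Axis:
    """Glenoid mediolateral axis: from the glenoid center toward the center
    of the best-fit sphere of the glenoid surface (medially directed, into
    the bone).  ``sphere`` may pass a pre-computed fit."""
    gc = np.asarray(glenoid_center, dtype=float).reshape(3)
    if sphere is None:
        sphere = fit_sphere(mesh.region_vertices("glenoid"))
    d = sphere.center - gc
    n = float(np.linalg.norm(d))
    if n < 1e-9:
        raise DegenerateGeometryError(
            "glenoid_axis: glenoid center coincides with the sphere center"
        )
    return Axis(point=gc, direction=d / n)


def measurement_frame(
    mesh: ScapulaMesh,
    transverse: Axis,
    inferior_angle: np.ndarray,
    glenoid_center: np.ndarray,
    frontal: Optional[Plane] = None,
) -> MeasurementFrame:
    """Orthonormal in-plane frame fixing the sign of the inclination.

    ``lateral_dir`` is the projected transverse direction; ``superior_dir``
    is the projection of (glenoid center - inferior angle) orthogonalized
    against ``lateral_dir``.
    """
    if frontal is None:
        frontal = frontal_plane(mesh)
    gc = np.asarray(glenoid_center, dtype=float).reshape(3)
    ia = np.asarray(inferior_angle, dtype=float).reshape(3)
    lateral = project_direction(transverse.direction, frontal)
    up = gc - ia
    if float(np.linalg.norm(up)) < 1e-9:
        raise DegenerateGeometryError(
            "measurement_frame: inferior angle coincides with the glenoid center"
        )
    sup = project_direction(up, frontal)
    sup = sup - (sup @ lateral) * lateral
    n = float(np.linalg.norm(sup))
    if n < 1e-6:
        raise DegenerateGeometryError(
            "measurement_frame: superior reference is parallel to the lateral direction"
        )
    return MeasurementFrame(frontal_plane=frontal, superior_dir=sup / n, lateral_dir=lateral)


def inclination(
    transverse: Axis,
    glenoid_ml: Axis,
    frame: MeasurementFrame,
    method: str = "y_axis",
) -> InclinationResult:
    """Signed glenoid inclination in degrees.

    Both axes are projected onto the frontal plane; the glenoid mediolateral
    axis (stored medially directed) is reversed so both projections point
    laterally; the angle is signed positive when the glenoid's lateral
    direction has a positive component along ``superior_dir`` — i.e. a
    superiorly-facing glenoid reads positive on either side of the body.
    """
    plane = frame.frontal_plane
    t = project_direction(transverse.direction, plane)
    t = _orient(t, frame.lateral_dir)
    g = -project_direction(glenoid_ml.direction, plane)  # lateral representative
    # reference normal chosen so that +angle == toward superior_dir
    ref = np.cross(frame.lateral_dir, frame.superior_dir)
    angle = signed_angle(t, g, ref)
    return InclinationResult(
        method=method,
        inclination_deg=angle,
        transverse_axis=transverse,
        glenoid_axis=glenoid_ml,
        frontal_plane=plane,
        frame=frame,
    )


def measure_inclination(
    mesh: ScapulaMesh,
    landmarks: LandmarkSet,
    method: str,
    frontal: Optional[Plane] = None,
    boundary_line: Optional[Axis] = None,
    sphere: Optional[Sphere] = None,
) -> InclinationResult:
    """End-to-end measurement for one mesh + one landmark set.

    The optional ``frontal``/``boundary_line``/``sphere`` arguments let a
    batch caller reuse the rater-independent fits; results are identical to
    recomputing them.
    """
    gc = glenoid_center(landmarks)
    if method == "y_axis":
        transverse = y_axis(mesh, gc, boundary_line=boundary_line)
    elif method == "gt_line":
        transverse = gt_line(gc, landmarks.trigonum)
    elif method == "bflf":
        transverse = bflf_axis(landmarks, gc)
    else:
        raise ValueError(f"unknown method {method!r}; expected y_axis, gt_line or bflf")
    g_ml = glenoid_axis(mesh, gc, sphere=sphere)
    frame = measurement_frame(mesh, transverse, landmarks.inferior_angle, gc, frontal=frontal)
    return inclination(transverse, g_ml, frame, method=method)
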