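"""Total-least-squares geometric primitives.

Plane and line fits minimise summed squared *orthogonal* distances
(orthogonal-distance regression via the eigen-structure of the centered
point cloud), not a coordinate regression, so the results are equivariant
under rigid motions and independent of any axis convention.  The sphere fit
seeds a geometric least-squares refinement with the standard algebraic
(linear) solution, because purely algebraic fits are biased on shallow caps
such as glenoid surfaces.

Direction/normal signs are canonicalized (first nonzero component positive);
anatomical orientation is applied by the callers in
:mod:`glenax.inclination`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError
from .types import Axis, Plane, Sphere

__all__ = [
    "fit_plane",
    "fit_line",
    "fit_sphere",
    "project_direction",
    "signed_angle",
    "canonical_sign",
]


def _points(points, min_n: int, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateGeometryError(f"{what}: expected (n, 3) points, got shape {pts.shape}")
    if len(pts) < min_n:
        raise DegenerateGeometryError(f"{what}: needs at least {min_n} points, got {len(pts)}")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError(f"{what}: non-finite coordinates")
    return pts


def canonical_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip ``v`` so its first component with magnitude > tol is positive."""
    for x in v:
        if abs(x) > tol:
            return v if x > 0 else -v
    return v


def fit_plane(points) -> Plane:
    """Best-fit plane through >= 3 non-collinear points.

    The plane passes through the centroid; its normal is the least-variance
    principal direction of the centered cloud, which minimises the sum of
    squared orthogonal distances.
    """
    pts = _points(points, 3, "fit_plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # singular values sorted descending; rows of vt are principal directions
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-12 * scale:
        raise DegenerateGeometryError("fit_plane: points are collinear (or coincident)")
    normal = canonical_sign(vt[2])
    return Plane(point=centroid, normal=normal)


def fit_line(points) -> Axis:
    """Best-fit line through >= 2 distinct points (principal axis of the
    centered cloud; minimises summed squared orthogonal distances)."""
    pts = _points(points, 2, "fit_line")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, float(np.abs(pts).max())):
        raise DegenerateGeometryError("fit_line: all points coincide")
    direction = canonical_sign(vt[0])
    return Axis(point=centroid, direction=direction)


def _sphere_residuals(x: np.ndarray, pts: np.ndarray) -> np.ndarray:
    c, r = x[:3], x[3]
    return np.linalg.norm(pts - c, axis=1) - r


def fit_sphere(points) -> Sphere:
    """Best-fit sphere to >= 4 non-coplanar points.

    Algebraic linear least-squares initialisation followed by geometric
    refinement of ``sum((|p - c| - r)^2)`` with Levenberg-Marquardt; the
    refinement is converged to machine precision (step tolerance 1e-15,
    far below the 1e-10 mm contract).
    """
    pts = _points(points, 4, "fit_sphere")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("fit_sphere: points are (nearly) coplanar")
    # algebraic seed: |p|^2 = 2 p.c + (r^2 - |c|^2), linear in (c, d)
    a = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    c0, d0 = sol[:3], sol[3]
    r0 = float(np.sqrt(max(d0 + c0 @ c0, 1e-12)))
    res = least_squares(
        _sphere_residuals,
        x0=np.append(c0, r0),
        args=(pts,),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    c, r = res.x[:3], float(res.x[3])
    if r < 0:  # LM is unconstrained; a negative radius is the mirrored optimum
        r = -r
    return Sphere(center=c, radius=r)


def project_direction(direction, plane: Plane) -> np.ndarray:
    """Unit component of ``direction`` within ``plane``.

    Raises if the direction is (numerically) parallel to the plane normal,
    in which case the projection is undefined.
    """
    d = np.asarray(direction, dtype=float).reshape(3)
    d = d / np.linalg.norm(d)
    w = d - (d @ plane.normal) * plane.normal
    n = float(np.linalg.norm(w))
    if n < 1e-6:
        raise DegenerateGeometryError(
            "project_direction: direction is parallel to the plane normal"
        )
    return w / n


def signed_angle(u, v, reference_normal) -> float:
    """Signed angle (degrees, in (-180, 180]) from ``u`` to ``v`` about
    ``reference_normal`` by the right-hand rule.

    Both vectors must lie in the plane orthogonal to ``reference_normal``
    (checked to 1e-6).
    """
    u = np.asarray(u, dtype=float).reshape(3)
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.asarray(reference_normal, dtype=float).reshape(3)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    n = n / np.linalg.norm(n)
    if abs(float(u @ n)) > 1e-6 or abs(float(v @ n)) > 1e-6:
        raise DegenerateGeometryError(
            "signed_angle: inputs must lie in the plane of the reference normal"
        )
    ang = float(np.degrees(np.arctan2(np.cross(u, v) @ n, u @ v)))
    if ang <= -180.0:
        ang += 360.0
    return ang
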