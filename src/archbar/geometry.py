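"""Exact 3D primitives for reference-bar metrology.

All coordinates are in millimetres in a right-handed model frame.  The
conventions here exist so that downstream angle formulas (arccos of dot
products) never see an arbitrarily flipped direction: every plane normal is
oriented by a caller-supplied outward hint, and every line direction is
canonicalised to have a positive X component (falling back to Y, then Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Cross/dot products below this are treated as parallel (degenerate).
PARALLEL_TOL = 1e-6
#: Geometric identity assertions (point-on-plane etc.) hold to this, in mm.
GEOM_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a construction is undefined (collinear points, parallel
    planes, line parallel to plane, zero-length direction)."""


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite 3-vector: {a}")
    return a


def unit(v) -> np.ndarray:
    """Normalise ``v`` to unit length; degenerate if its norm is ~0."""
    a = _as_vec3(v)
    n = np.linalg.norm(a)
    if n < PARALLEL_TOL:
        raise DegenerateGeometryError("cannot normalise near-zero vector")
    return a / n


def orient_direction(d) -> np.ndarray:
    """Canonical sign for a line direction: first of (X, Y, Z) components
    with magnitude above ``GEOM_TOL`` is made positive."""
    d = unit(d)
    for i in range(3):
        if abs(d[i]) > GEOM_TOL:
            return d if d[i] > 0 else -d
    raise DegenerateGeometryError("zero direction")  # pragma: no cover


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane: any point on it plus a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = (p - self.point) @ self.normal
        return d[0] if np.asarray(points).ndim == 1 else d

    def translated(self, direction, distance_mm: float) -> "Plane":
        """Parallel shift by ``distance_mm`` along ``direction`` (unit)."""
        return Plane(self.point + float(distance_mm) * unit(direction), self.normal)

    def transformed(self, rotation: np.ndarray, translation) -> "Plane":
        """Image of the plane under the rigid map x -> R x + t."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(translation)
        return Plane(R @ self.point + t, R @ self.normal)


@dataclass(frozen=True)
class Line3:
    """3D line: a point plus a unit direction (canonical sign)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point))
        object.__setattr__(self, "direction", orient_direction(self.direction))

    def at(self, t: float) -> np.ndarray:
        return self.point + float(t) * self.direction


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed orthonormal frame: X transversal (left-right along the
    bar), Y anterior-posterior, Z vertical.  ``axes`` rows are X, Y, Z
    expressed in world coordinates."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame must be right-handed")
        object.__setattr__(self, "axes", A)

    def to_local(self, points) -> np.ndarray:
        """World coordinates -> frame coordinates."""
        p = np.asarray(points, dtype=float)
        return (p - self.origin) @ self.axes.T

    def to_world(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.axes + self.origin

    def transformed(self, rotation: np.ndarray, translation) -> "ReferenceFrame":
        """Frame carried along by the rigid map x -> R x + t."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        return ReferenceFrame(R @ self.origin + _as_vec3(translation),
                              self.axes @ R.T)


def fit_plane(points, outward_hint=None) -> Plane:
    """Orthogonal least-squares plane through ``points``.

    Minimises the sum of squared perpendicular distances; the normal is the
    singular vector of the centred point cloud with the smallest singular
    value.  ``outward_hint`` fixes the normal sign (positive dot product).

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or a
    (near-)collinear point set.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array-like")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"plane fit needs >= 3 points, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centred cloud; s[1] ~ 0 means the points span only a line.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= max(s[0] * 1e-12, GEOM_TOL):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = vt[2]
    if outward_hint is not None:
        h = _as_vec3(outward_hint)
        if float(normal @ h) < 0:
            normal = -normal
    return Plane(centroid, normal)


def plane_fit_rms(plane: Plane, points) -> float:
    """RMS orthogonal residual of ``points`` about ``plane`` (mm)."""
    d = plane.signed_distance(points)
    return float(np.sqrt(np.mean(np.square(d))))


def intersect_planes(a: Plane, b: Plane) -> Line3:
    """Line of intersection of two non-parallel planes.

    The returned point is the one on the line closest to ``a.point``; the
    direction carries the canonical sign.
    """
    d = np.cross(a.normal, b.normal)
    nd = np.linalg.norm(d)
    if nd < PARALLEL_TOL:
        raise DegenerateGeometryError(
            f"planes are (near-)parallel: |n_a x n_b| = {nd:.2e}")
    d = d / nd
    # Solve for the point: on both planes, and in the plane through a.point
    # perpendicular to the line (picks the closest point to a.point).
    A = np.vstack([a.normal, b.normal, d])
    rhs = np.array([a.normal @ a.point, b.normal @ b.point, d @ a.point])
    point = np.linalg.solve(A, rhs)
    return Line3(point, d)


def intersect_line_plane(line: Line3, plane: Plane) -> np.ndarray:
    """Intersection point of a line and a plane (degenerate if parallel)."""
    denom = float(line.direction @ plane.normal)
    if abs(denom) < PARALLEL_TOL:
        raise DegenerateGeometryError(
            f"line is (near-)parallel to plane: |d.n| = {abs(denom):.2e}")
    t = float((plane.point - line.point) @ plane.normal) / denom
    return line.at(t)


def translate_plane(p: Plane, direction, distance_mm: float) -> Plane:
    """Parallel shift of ``p`` by ``distance_mm`` along ``direction``."""
    return p.translated(direction, distance_mm)


def rotation_matrix_xyz(angles_deg) -> np.ndarray:
    """Rotation matrix for extrinsic rotations about X, then Y, then Z,
    with angles in degrees: R = Rz @ Ry @ Rx."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float).reshape(3))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx
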