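"""Shared geometric primitives: heading angles, quaternions, floor planes.

All headings in this package are measured in degrees, counterclockwise from
the relevant frame's x-axis when viewed from above, and wrapped to [0, 360).
Quaternions are scalar-first ``(w, x, y, z)`` unit quaternions acting on
column vectors by conjugation, ``v' = q v q*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "wrap_heading",
    "signed_angle_diff",
    "quat_identity",
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_to_matrix",
    "quat_from_matrix",
    "Plane",
    "fit_floor_plane",
    "TrackingFrame",
    "make_tracking_frame",
]


def wrap_heading(angle: float) -> float:
    """Wrap an angle in degrees into [0, 360)."""
    angle = float(angle)
    if not np.isfinite(angle):
        raise ValueError(f"non-finite heading: {angle}")
    r = angle % 360.0
    return 0.0 if r == 360.0 else r  # float mod of tiny negatives gives 360.0


def signed_angle_diff(a: float, b: float) -> float:
    """Minimal signed difference ``a - b`` in degrees, in (-180, 180].

    The antipodal case returns +180.
    """
    a, b = float(a), float(b)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("non-finite angle")
    d = (a - b) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


# ---------------------------------------------------------------------------
# Quaternions


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def quat_multiply(p, q) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vector ``v`` by unit quaternion ``q`` (``v' = q v q*``)."""
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise ValueError("quaternion is not normalized")
    v = np.asarray(v, dtype=float)
    # Rodrigues-style expansion, cheaper than two quaternion products.
    w, u = q[0], q[1:]
    return v + 2.0 * np.cross(u, np.cross(u, v) + w * v)


def quat_from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("zero rotation axis")
    axis = axis / n
    half = 0.5 * float(angle_rad)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_from_matrix(m) -> np.ndarray:
    """Unit quaternion for a proper rotation matrix (Shepperd's method)."""
    m = np.asarray(m, dtype=float)
    tr = m[0, 0] + m[1, 1] + m[2, 2]
    if tr > 0:
        s = 2.0 * np.sqrt(tr + 1.0)
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    else:
        i = int(np.argmax([m[0, 0], m[1, 1], m[2, 2]]))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = 2.0 * np.sqrt(max(1.0 + m[i, i] - m[j, j] - m[k, k], 0.0))
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    return quat_normalize(q)


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix R with ``R v == quat_rotate(q, v)``."""
    w, x, y, z = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# Floor plane


@dataclass(frozen=True)
class Plane:
    """Plane ``normal . p + offset = 0`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0.0:
            raise ValueError("zero plane normal")
        object.__setattr__(self, "normal", n / nn)
        object.__setattr__(self, "offset", float(self.offset) / nn)

    def signed_distance(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.normal + self.offset

    def project(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        d = self.signed_distance(points)
        return np.atleast_2d(points) - np.outer(d, self.normal)


def _lstsq_plane(points: np.ndarray) -> Plane:
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if s[-2] < 1e-12 * max(s[0], 1e-30):
        raise ValueError("points are collinear; plane is underdetermined")
    normal = vt[-1]
    return Plane(normal=normal, offset=-float(normal @ centroid))


def fit_floor_plane(
    points,
    inlier_tol: float = 0.02,
    seed: int | np.random.Generator = 0,
    n_iter: int = 200,
    min_inlier_frac: float = 0.5,
    orient_toward=None,
) -> Plane:
    """Robust consensus (RANSAC) floor-plane fit, least-squares refined.

    Parameters
    ----------
    points : (N, 3) array
        Candidate floor points, N >= 3 and non-collinear.
    inlier_tol : float
        Point-to-plane distance (m) below which a point counts as an inlier.
    seed : int or Generator
        Seeds the consensus sampling; the fit is deterministic per seed.
    min_inlier_frac : float
        Minimum fraction of inliers for a consensus to be accepted.
    orient_toward : 3-vector, optional
        A point on the camera side of the floor; the returned normal is
        flipped to point toward it (positive signed distance).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise ValueError("need an (N, 3) array with N >= 3")
    rng = np.random.default_rng(seed)

    best_inliers = None
    best_count = 0
    n = len(points)
    for _ in range(n_iter):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = points[idx]
        nvec = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nvec)
        if norm < 1e-12:
            continue
        nvec = nvec / norm
        d = np.abs((points - p0) @ nvec)
        inliers = d <= inlier_tol
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers

    if best_inliers is None or best_count < max(3, min_inlier_frac * n):
        raise ValueError(
            "no plane consensus above the minimum inlier fraction "
            f"({best_count}/{n} inliers)"
        )
    plane = _lstsq_plane(points[best_inliers])
    if orient_toward is not None:
        if plane.signed_distance(orient_toward)[0] < 0:
            plane = Plane(normal=-plane.normal, offset=-plane.offset)
    return plane


# ---------------------------------------------------------------------------
# Tracking frame


@dataclass(frozen=True)
class TrackingFrame:
    """2D floor coordinate frame anchored at the floor point below the camera.

    ``x_axis``/``y_axis`` span the floor plane; ``z_axis`` is the floor
    normal pointing up toward the camera. ``y_axis`` is the in-plane
    projection of the camera's forward (yc) direction. ``psi_deg`` is the
    rig-calibrated angle from magnetic North to the yc-axis, measured
    counterclockwise viewed from above.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    psi_deg: float | None = None

    def to_frame(self, points) -> np.ndarray:
        """World/camera coordinates -> (x, y, height) frame coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rel = points - self.origin
        return np.column_stack(
            [rel @ self.x_axis, rel @ self.y_axis, rel @ self.z_axis]
        )

    def to_world(self, coords) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.shape[1] == 2:
            coords = np.column_stack([coords, np.zeros(len(coords))])
        return (
            self.origin
            + np.outer(coords[:, 0], self.x_axis)
            + np.outer(coords[:, 1], self.y_axis)
            + np.outer(coords[:, 2], self.z_axis)
        )


def make_tracking_frame(
    plane: Plane, camera_origin, camera_forward, psi_deg: float | None = None
) -> TrackingFrame:
    """Build the camera's floor tracking frame from the fitted floor plane.

    The origin is the orthogonal projection of the camera center onto the
    floor; the y-axis is the in-plane projection of the camera forward
    direction; the x-axis completes a right-handed basis (x = y cross z
    inverted: x = y x z so that z is up and headings are CCW from x).
    """
    camera_origin = np.asarray(camera_origin, dtype=float)
    camera_forward = np.asarray(camera_forward, dtype=float)
    d_cam = plane.signed_distance(camera_origin)[0]
    if abs(d_cam) < 1e-9:
        raise ValueError("camera origin lies on the floor plane")
    # z up toward the camera
    z_axis = plane.normal if d_cam > 0 else -plane.normal
    fwd_in_plane = camera_forward - (camera_forward @ z_axis) * z_axis
    n_fwd = np.linalg.norm(fwd_in_plane)
    if n_fwd < 1e-9 * np.linalg.norm(camera_forward):
        raise ValueError("camera forward direction is parallel to the floor normal")
    y_axis = fwd_in_plane / n_fwd
    x_axis = np.cross(y_axis, z_axis)
    origin = plane.project(camera_origin)[0]
    return TrackingFrame(
        origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis, psi_deg=psi_deg
    )
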