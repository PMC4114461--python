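"""Quaternion orientation filters for the worn inertial device.

Two variants of the gradient-descent complementary filter are provided:

* **GROE** (gravity-relative orientation estimation) fuses gyroscope and
  accelerometer only. It observes tilt with respect to gravity; the yaw
  component is pure gyro integration and its zero point is arbitrary
  (fixed by the initial quaternion).
* **AOE** (absolute orientation estimation) additionally fuses a tri-axis
  magnetometer and converges to the absolute orientation in the world
  frame spanned by gravity and magnetic North. Its world x-axis points
  along the horizontal component of the magnetic field (North) and its
  z-axis points up.

Quaternions map device-frame vectors into the filter's world frame,
``v_world = q (0, v_dev) q*``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import quat_from_matrix, quat_rotate, wrap_heading

__all__ = [
    "ImuSample",
    "OrientationEstimate",
    "ProjectedAxes",
    "groe_step",
    "aoe_step",
    "run_filter",
    "project_device_axes",
    "device_heading_alpha",
    "heading_series",
    "triad_attitude",
    "GROE_BETA_DEFAULT",
    "AOE_BETA_DEFAULT",
]

#: Filter gains. The gradient-descent step size trades convergence speed
#: against noise feed-through; these sit in the range recommended for
#: consumer-grade MEMS sensors sampled at ~100 Hz.
GROE_BETA_DEFAULT = 0.1
AOE_BETA_DEFAULT = 0.041


@dataclass(frozen=True)
class ImuSample:
    """One inertial sample: time (s), angular rate (rad/s), specific force
    (m/s^2), optional magnetic field (any consistent unit; normalized
    before use)."""

    t: float
    angular_rate: np.ndarray
    specific_force: np.ndarray
    magnetic_field: np.ndarray | None = None


@dataclass(frozen=True)
class OrientationEstimate:
    """Unit quaternion (device -> world) stamped with its sample time."""

    q: np.ndarray
    t: float


@dataclass(frozen=True)
class ProjectedAxes:
    """Device y/z axes orthogonally projected into the floor plane, plus
    the heading ``theta_i`` (deg, CCW from the reference x-axis) of y'."""

    y_prime: np.ndarray
    z_prime: np.ndarray
    theta_i: float


# ---------------------------------------------------------------------------
# Scalar-core update steps. These run once per sample in long streams, so
# they are written with plain floats rather than numpy vectors.


def _groe_update(q0, q1, q2, q3, gx, gy, gz, ax, ay, az, beta, dt):
    # quaternion derivative from gyro
    qDot0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
    qDot1 = 0.5 * (q0 * gx + q2 * gz - q3 * gy)
    qDot2 = 0.5 * (q0 * gy - q1 * gz + q3 * gx)
    qDot3 = 0.5 * (q0 * gz + q1 * gy - q2 * gx)

    norm_a = math.sqrt(ax * ax + ay * ay + az * az)
    if norm_a > 0.0 and beta > 0.0:
        ax, ay, az = ax / norm_a, ay / norm_a, az / norm_a
        # objective: rotate world +z (up) into device frame, compare to accel
        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
        s0 = -2.0 * q2 * f1 + 2.0 * q1 * f2
        s1 = 2.0 * q3 * f1 + 2.0 * q0 * f2 - 4.0 * q1 * f3
        s2 = -2.0 * q0 * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
        s3 = 2.0 * q1 * f1 + 2.0 * q2 * f2
        norm_s = math.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
        if norm_s > 1e-12:
            qDot0 -= beta * s0 / norm_s
            qDot1 -= beta * s1 / norm_s
            qDot2 -= beta * s2 / norm_s
            qDot3 -= beta * s3 / norm_s

    q0 += qDot0 * dt
    q1 += qDot1 * dt
    q2 += qDot2 * dt
    q3 += qDot3 * dt
    norm_q = math.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    return q0 / norm_q, q1 / norm_q, q2 / norm_q, q3 / norm_q


def _aoe_update(q0, q1, q2, q3, gx, gy, gz, ax, ay, az, mx, my, mz, beta, dt):
    qDot0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
    qDot1 = 0.5 * (q0 * gx + q2 * gz - q3 * gy)
    qDot2 = 0.5 * (q0 * gy - q1 * gz + q3 * gx)
    qDot3 = 0.5 * (q0 * gz + q1 * gy - q2 * gx)

    norm_a = math.sqrt(ax * ax + ay * ay + az * az)
    norm_m = math.sqrt(mx * mx + my * my + mz * mz)
    if norm_a > 0.0 and norm_m > 0.0 and beta > 0.0:
        ax, ay, az = ax / norm_a, ay / norm_a, az / norm_a
        mx, my, mz = mx / norm_m, my / norm_m, mz / norm_m

        # magnetic field in the world frame; its horizontal part defines
        # the North reference b = (bx, 0, bz)
        hx = mx * (q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3) + 2.0 * my * (
            q1 * q2 - q0 * q3
        ) + 2.0 * mz * (q1 * q3 + q0 * q2)
        hy = 2.0 * mx * (q1 * q2 + q0 * q3) + my * (
            q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3
        ) + 2.0 * mz * (q2 * q3 - q0 * q1)
        hz = 2.0 * mx * (q1 * q3 - q0 * q2) + 2.0 * my * (
            q2 * q3 + q0 * q1
        ) + mz * (q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3)
        bx = math.sqrt(hx * hx + hy * hy)
        bz = hz

        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
        f4 = 2.0 * bx * (0.5 - q2 * q2 - q3 * q3) + 2.0 * bz * (
            q1 * q3 - q0 * q2
        ) - mx
        f5 = 2.0 * bx * (q1 * q2 - q0 * q3) + 2.0 * bz * (q0 * q1 + q2 * q3) - my
        f6 = 2.0 * bx * (q0 * q2 + q1 * q3) + 2.0 * bz * (
            0.5 - q1 * q1 - q2 * q2
        ) - mz

        s0 = (
            -2.0 * q2 * f1
            + 2.0 * q1 * f2
            - 2.0 * bz * q2 * f4
            + (-2.0 * bx * q3 + 2.0 * bz * q1) * f5
            + 2.0 * bx * q2 * f6
        )
        s1 = (
            2.0 * q3 * f1
            + 2.0 * q0 * f2
            - 4.0 * q1 * f3
            + 2.0 * bz * q3 * f4
            + (2.0 * bx * q2 + 2.0 * bz * q0) * f5
            + (2.0 * bx * q3 - 4.0 * bz * q1) * f6
        )
        s2 = (
            -2.0 * q0 * f1
            + 2.0 * q3 * f2
            - 4.0 * q2 * f3
            + (-4.0 * bx * q2 - 2.0 * bz * q0) * f4
            + (2.0 * bx * q1 + 2.0 * bz * q3) * f5
            + (2.0 * bx * q0 - 4.0 * bz * q2) * f6
        )
        s3 = (
            2.0 * q1 * f1
            + 2.0 * q2 * f2
            + (-4.0 * bx * q3 + 2.0 * bz * q1) * f4
            + (-2.0 * bx * q0 + 2.0 * bz * q2) * f5
            + 2.0 * bx * q1 * f6
        )
        norm_s = math.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
        if norm_s > 1e-12:
            qDot0 -= beta * s0 / norm_s
            qDot1 -= beta * s1 / norm_s
            qDot2 -= beta * s2 / norm_s
            qDot3 -= beta * s3 / norm_s

    q0 += qDot0 * dt
    q1 += qDot1 * dt
    q2 += qDot2 * dt
    q3 += qDot3 * dt
    norm_q = math.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    return q0 / norm_q, q1 / norm_q, q2 / norm_q, q3 / norm_q


def groe_step(
    est: OrientationEstimate, sample: ImuSample, beta: float = GROE_BETA_DEFAULT
) -> OrientationEstimate:
    """Advance the gravity-relative filter by one IMU sample.

    Gyro rates are integrated and the tilt is nudged toward the
    accelerometer-implied gravity direction by one normalized
    gradient-descent step of size ``beta``. Zero specific force skips the
    correction (pure integration).
    """
    dt = sample.t - est.t
    if dt <= 0:
        raise ValueError(f"non-increasing sample time (dt={dt})")
    g = np.asarray(sample.angular_rate, dtype=float)
    a = np.asarray(sample.specific_force, dtype=float)
    q = _groe_update(*est.q, g[0], g[1], g[2], a[0], a[1], a[2], beta, dt)
    return OrientationEstimate(q=np.array(q), t=sample.t)


def aoe_step(
    est: OrientationEstimate, sample: ImuSample, beta: float = AOE_BETA_DEFAULT
) -> OrientationEstimate:
    """Advance the absolute (MARG) filter by one sample.

    Requires a magnetic-field measurement; callers with IMU-only streams
    should use :func:`groe_step`.
    """
    dt = sample.t - est.t
    if dt <= 0:
        raise ValueError(f"non-increasing sample time (dt={dt})")
    if sample.magnetic_field is None:
        raise ValueError("sample has no magnetic field; use groe_step for IMU-only data")
    m = np.asarray(sample.magnetic_field, dtype=float)
    if not np.any(m):
        raise ValueError("zero magnetic field; use groe_step for IMU-only data")
    g = np.asarray(sample.angular_rate, dtype=float)
    a = np.asarray(sample.specific_force, dtype=float)
    q = _aoe_update(
        *est.q, g[0], g[1], g[2], a[0], a[1], a[2], m[0], m[1], m[2], beta, dt
    )
    return OrientationEstimate(q=np.array(q), t=sample.t)


def run_filter(
    t,
    gyro,
    accel,
    mag=None,
    mode: str = "groe",
    beta: float | None = None,
    q0=None,
) -> np.ndarray:
    """Run a full stream through the chosen filter.

    Parameters
    ----------
    t : (N,) times in s (strictly increasing)
    gyro, accel : (N, 3) arrays
    mag : (N, 3) array, required for ``mode="aoe"``
    q0 : initial quaternion; by default the closed-form attitude from the
        first sample (TRIAD for AOE, tilt-only for GROE), which removes
        the slow large-angle convergence of a cold identity start

    Returns
    -------
    (N, 4) array of unit quaternions (device -> world), one per sample.
    The first sample only sets the clock (its output is ``q0``).
    """
    t = np.asarray(t, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    accel = np.asarray(accel, dtype=float)
    if mode == "aoe":
        if mag is None:
            raise ValueError("AOE mode requires magnetometer data")
        mag = np.asarray(mag, dtype=float)
        if beta is None:
            beta = AOE_BETA_DEFAULT
    elif mode == "groe":
        if beta is None:
            beta = GROE_BETA_DEFAULT
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = len(t)
    out = np.empty((n, 4))
    if q0 is None:
        try:
            q = tuple(
                triad_attitude(accel[0], mag[0] if mode == "aoe" else None)
            )
        except ValueError:
            q = (1.0, 0.0, 0.0, 0.0)
    else:
        q0 = np.asarray(q0, dtype=float)
        q = tuple(q0 / np.linalg.norm(q0))
    out[0] = q
    tg = t.tolist()
    gy = gyro.tolist()
    ac = accel.tolist()
    if mode == "aoe":
        mg = mag.tolist()
        for i in range(1, n):
            dt = tg[i] - tg[i - 1]
            if dt <= 0:
                raise ValueError("sample times must be strictly increasing")
            q = _aoe_update(*q, *gy[i], *ac[i], *mg[i], beta, dt)
            out[i] = q
    else:
        for i in range(1, n):
            dt = tg[i] - tg[i - 1]
            if dt <= 0:
                raise ValueError("sample times must be strictly increasing")
            q = _groe_update(*q, *gy[i], *ac[i], beta, dt)
            out[i] = q
    return out


def triad_attitude(accel, mag=None) -> np.ndarray:
    """Closed-form attitude (device -> world quaternion) from one static
    accelerometer sample and, optionally, one magnetometer sample.

    With both references this is the TRIAD solution in the gravity/North
    world frame (x = horizontal field component, z = up). With the
    accelerometer alone the yaw is chosen so the device x-axis's
    horizontal projection lies along world x (tilt-only attitude).
    """
    a = np.asarray(accel, dtype=float)
    na = np.linalg.norm(a)
    if na == 0:
        raise ValueError("zero specific force; attitude undefined")
    up_d = a / na  # world +z in device coords
    if mag is not None:
        m = np.asarray(mag, dtype=float)
        m = m / np.linalg.norm(m)
        x_d = m - (m @ up_d) * up_d  # horizontal field = North
    else:
        # gauge choice: any horizontal direction; prefer one orthogonal
        # to up that is stable for our mounting (device y roughly
        # horizontal)
        seed_axis = np.array([0.0, 1.0, 0.0])
        if abs(seed_axis @ up_d) > 0.9:
            seed_axis = np.array([0.0, 0.0, 1.0])
        x_d = seed_axis - (seed_axis @ up_d) * up_d
    nx = np.linalg.norm(x_d)
    if nx < 1e-9:
        raise ValueError("reference vectors are parallel; attitude undefined")
    x_d = x_d / nx
    y_d = np.cross(up_d, x_d)
    # rows of R(device->world) are the world axes in device coordinates
    return quat_from_matrix(np.vstack([x_d, y_d, up_d]))


# ---------------------------------------------------------------------------
# Floor-plane projections


def _project_axis(q, axis, x_ref, y_ref, normal):
    v_world = quat_rotate(q, axis)
    if abs(float(v_world @ normal)) > math.cos(math.radians(5.0)):
        raise ValueError(
            "device axis within 5 degrees of the floor normal; projection degenerate"
        )
    v = v_world - (v_world @ normal) * normal
    v = v / np.linalg.norm(v)
    theta = wrap_heading(math.degrees(math.atan2(float(v @ y_ref), float(v @ x_ref))))
    return v, theta


def project_device_axes(est: OrientationEstimate, frame=None) -> ProjectedAxes:
    """Project the device y and z axes into the floor plane.

    ``frame`` is a :class:`~fogpose.geometry.TrackingFrame` whose axes are
    expressed in the same world frame as the orientation estimate. When
    omitted, the estimate's own world frame is used (z up, headings
    measured from its x-axis) -- the natural choice for GROE output whose
    yaw gauge is arbitrary and later absorbed by the correction angle.
    """
    if frame is None:
        x_ref = np.array([1.0, 0.0, 0.0])
        y_ref = np.array([0.0, 1.0, 0.0])
        normal = np.array([0.0, 0.0, 1.0])
    else:
        x_ref, y_ref, normal = frame.x_axis, frame.y_axis, frame.z_axis
    y_prime, theta_i = _project_axis(est.q, np.array([0.0, 1.0, 0.0]), x_ref, y_ref, normal)
    try:
        z_prime, _ = _project_axis(est.q, np.array([0.0, 0.0, 1.0]), x_ref, y_ref, normal)
    except ValueError:
        z_prime = np.cross(normal, y_prime)  # degenerate z; y' already fixed
    return ProjectedAxes(y_prime=y_prime, z_prime=z_prime, theta_i=theta_i)


def device_heading_alpha(est: OrientationEstimate) -> float:
    """Heading alpha of the device y-axis relative to magnetic North.

    Valid for AOE estimates, whose world x-axis is the horizontal
    component of the magnetic field. Measured counterclockwise (viewed
    from above) from North, in [0, 360).
    """
    return project_device_axes(est).theta_i


def heading_series(quats: np.ndarray, alpha: bool = False) -> np.ndarray:
    """Vectorized heading (deg, CCW from world x) of the projected device
    y-axis for an (N, 4) quaternion array; NaN where the projection is
    degenerate. For AOE quaternions this is the alpha angle."""
    q = np.asarray(quats, dtype=float)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # world coords of device y-axis = R(q)[:, 1]
    yx = 2.0 * (x * y - w * z)
    yy = 1.0 - 2.0 * (x * x + z * z)
    yz = 2.0 * (y * z + w * x)
    out = np.mod(np.degrees(np.arctan2(yy, yx)), 360.0)
    horiz = np.hypot(yx, yy)
    out[np.abs(yz) > horiz * np.tan(np.radians(85.0))] = np.nan
    return out
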