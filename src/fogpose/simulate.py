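"""Seeded synthetic sensor generator replicating the accuracy-assessment
protocol: an 8 x 5 m walking area observed by two depth cameras mounted at
2.25 m with a 25 degree downward pitch, and participants wearing a
waist-mounted MARG device sampled at 100 Hz.

Each participant executes two scripted walks per sensor-mount condition,
stopping for 3 s at marked reference points in prescribed orientations
(12 points per condition). Bodies are modeled as an elliptical-cylinder
torso plus a head sphere displaced toward the ventral side, which makes
front and back visually distinguishable in plan view. Depth noise grows
quadratically with range, as for structured-light sensors.

All outputs are deterministic functions of the configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .geometry import Plane, make_tracking_frame, wrap_heading
from .planview import DepthCamera

__all__ = [
    "BodyModel",
    "WalkScript",
    "SimConfig",
    "Participant",
    "WalkSimulation",
    "ExperimentSim",
    "REFERENCE_POINTS",
    "WALK_A",
    "WALK_B",
    "default_rig",
    "build_trajectory",
    "simulate_imu",
    "render_depth_frame",
    "generate_experiment",
    "generate_template_dataset",
]

G = 9.81

#: Reference stop points: id -> (x, y, heading) in the world frame of the
#: walking area (m, deg). These are the marker reference values the
#: evaluation compares against.
REFERENCE_POINTS = {
    1: (2.25, 1.75, 270.0),
    2: (3.25, 1.75, 0.0),
    3: (5.75, 3.00, 30.0),
    4: (3.25, 4.25, 180.0),
    5: (1.25, 4.25, 225.0),
    6: (1.75, 2.75, 330.0),
    7: (6.25, 1.75, 270.0),
    8: (4.75, 1.75, 180.0),
    9: (1.75, 2.75, 150.0),
    10: (1.25, 4.25, 45.0),
    11: (3.25, 4.25, 0.0),
    12: (6.75, 2.25, 330.0),
}


@dataclass(frozen=True)
class WalkScript:
    """Ordered stop points with a start/end position and walking speed."""

    point_ids: tuple
    start: tuple
    end: tuple
    speed: float = 0.8
    stop_duration: float = 3.0

    @property
    def waypoints(self):
        return [
            (REFERENCE_POINTS[p][0], REFERENCE_POINTS[p][1], REFERENCE_POINTS[p][2])
            for p in self.point_ids
        ]


#: Walk with predominantly left turns (points 1-6) and the walk with
#: predominantly right turns (points 7-12); together one sensor-mount
#: condition's 12 reference stops.
WALK_A = WalkScript(point_ids=(1, 2, 3, 4, 5, 6), start=(0.25, 1.75), end=(0.25, 2.75))
WALK_B = WalkScript(point_ids=(7, 8, 9, 10, 11, 12), start=(7.75, 1.75), end=(7.75, 2.25))


@dataclass(frozen=True)
class BodyModel:
    """Upright body: elliptical-cylinder torso plus a head sphere offset
    ``head_forward_offset`` toward the ventral side."""

    height: float
    shoulder_width: float = 0.45
    chest_depth: float = 0.26
    head_forward_offset: float = 0.04
    head_radius: float = 0.11

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.shoulder_width <= self.chest_depth:
            raise ValueError(
                "shoulder width must exceed chest depth (orientation anisotropy)"
            )

    @property
    def torso_top(self) -> float:
        return self.height - 2.0 * self.head_radius + 0.02


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic replication."""

    camera_height: float = 2.25
    pitch_deg: float = 25.0
    fps: float = 15.0
    imu_rate: float = 100.0
    depth_noise_coeff: float = 0.0019  # sigma(z) = coeff * z^2  [m]
    depth_dropout: float = 0.02
    gyro_noise: float = 0.005  # rad/s
    gyro_bias_std: float = 0.005  # rad/s, constant per stream
    accel_noise: float = 0.1  # m/s^2
    mag_noise: float = 0.02  # fraction of field magnitude
    north_deg: float = 25.0  # world azimuth of magnetic North
    mag_inclination_deg: float = 60.0
    walking_speed: float = 0.8  # m/s
    turn_rate_deg: float = 120.0  # on-the-spot turning rate
    stop_duration: float = 3.0
    mount_offset_deg: tuple | float = 0.0  # scalar or (lo, hi) uniform range
    mount_jitter_deg: float = 6.0  # per-participant placement azimuth sd
    mount_tilt_deg: float = 3.0  # per-participant tilt sd about horizontal axes
    placement_std_m: float = 0.08  # stand offset along the marker line
    placement_across_std_m: float = 0.04
    heading_jitter_deg: float = 4.0  # stand heading error vs the marker
    height_mean: float = 1.742
    height_std: float = 0.088

    @classmethod
    def noise_free(cls, **overrides) -> "SimConfig":
        """All sensor noise and human placement variability switched off
        (for self-consistency checks)."""
        base = dict(
            depth_noise_coeff=0.0,
            depth_dropout=0.0,
            gyro_noise=0.0,
            gyro_bias_std=0.0,
            accel_noise=0.0,
            mag_noise=0.0,
            mount_jitter_deg=0.0,
            mount_tilt_deg=0.0,
            placement_std_m=0.0,
            placement_across_std_m=0.0,
            heading_jitter_deg=0.0,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Camera rig


def default_rig(config: SimConfig):
    """The two-camera rig: non-overlapping coverage of the walking area.

    Both cameras hang just outside the long edge of the area, facing +y
    (world azimuth 90 degrees) with the configured height and pitch.
    Returns ``(cameras, frames)``; each tracking frame carries the
    rig-calibrated psi (CCW angle from magnetic North to the camera yc).
    """
    floor = Plane(normal=np.array([0.0, 0.0, 1.0]), offset=0.0)
    yaw = 90.0
    psi = wrap_heading(yaw - config.north_deg)
    cameras, frames = [], []
    for cx in (2.25, 5.75):
        pos = np.array([cx, -0.7, config.camera_height])
        cam = DepthCamera.from_yaw_pitch(pos, yaw, config.pitch_deg)
        fwd = cam.rotation[:, 2]  # optical axis in world coords
        frames.append(make_tracking_frame(floor, pos, fwd, psi_deg=psi))
        cameras.append(cam)
    return cameras, frames


def camera_yaw_deg(frame) -> float:
    """World azimuth of a tracking frame's y-axis (the camera yc)."""
    return wrap_heading(math.degrees(math.atan2(frame.y_axis[1], frame.y_axis[0])))


# ---------------------------------------------------------------------------
# Trajectory synthesis


@dataclass
class Trajectory:
    """Body trajectory sampled at the IMU rate, plus the stop annotations."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray  # continuous (unwrapped)
    stops: pd.DataFrame  # point_id, t_start, t_end, ref/actual pose


def _turn_span(h_from, h_to):
    d = (h_to - h_from + 180.0) % 360.0 - 180.0
    return d


def build_trajectory(
    script: WalkScript,
    config: SimConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Piecewise trajectory: turn on the spot toward each leg, walk at
    constant speed, turn to the marker heading, stand still.

    Human variability: the standing position is offset along the marker
    line (which runs perpendicular to the prescribed facing) and the
    standing heading is jittered; the truth table keeps the *reference*
    marker pose, as the protocol scores estimates against the markers.
    """
    dt = 1.0 / config.imu_rate
    speed = config.walking_speed
    turn_rate = config.turn_rate_deg

    segs = []  # (duration, fn(tau) -> (x, y, heading_unwrapped))
    stops = []

    pos = np.array(script.start, dtype=float)
    first = script.waypoints[0]
    heading = math.degrees(math.atan2(first[1] - pos[1], first[0] - pos[0]))

    def add_turn(h_to):
        nonlocal heading
        d = _turn_span(heading, h_to)
        dur = abs(d) / turn_rate
        if dur < dt:
            heading += d
            return
        h0, p = heading, pos.copy()
        segs.append(
            (dur, lambda tau, h0=h0, d=d, dur=dur, p=p: (p[0], p[1], h0 + d * tau / dur))
        )
        heading += d

    def add_walk(target):
        nonlocal pos
        vec = np.asarray(target, dtype=float) - pos
        dist = float(np.hypot(*vec))
        if dist < 1e-9:
            return
        dur = dist / speed
        p0, p1, h = pos.copy(), np.asarray(target, dtype=float), heading
        segs.append(
            (
                dur,
                lambda tau, p0=p0, p1=p1, dur=dur, h=h: (
                    p0[0] + (p1[0] - p0[0]) * tau / dur,
                    p0[1] + (p1[1] - p0[1]) * tau / dur,
                    h,
                ),
            )
        )
        pos = p1

    def add_stand(duration):
        p, h = pos.copy(), heading
        segs.append((duration, lambda tau, p=p, h=h: (p[0], p[1], h)))

    t_cursor = 0.0

    def total_time():
        return sum(d for d, _ in segs)

    for pid, (wx, wy, wh) in zip(script.point_ids, script.waypoints):
        # human placement: offset along the marker line, perpendicular to
        # the prescribed facing direction
        h_rad = math.radians(wh)
        perp = np.array([-math.sin(h_rad), math.cos(h_rad)])
        fwd = np.array([math.cos(h_rad), math.sin(h_rad)])
        lat = float(np.clip(rng.normal(0.0, config.placement_std_m), -0.22, 0.22)) if config.placement_std_m else 0.0
        lon = float(np.clip(rng.normal(0.0, config.placement_across_std_m), -0.1, 0.1)) if config.placement_across_std_m else 0.0
        act = np.array([wx, wy]) + lat * perp + lon * fwd
        act_h = wh + (rng.normal(0.0, config.heading_jitter_deg) if config.heading_jitter_deg else 0.0)

        leg_dir = math.degrees(math.atan2(act[1] - pos[1], act[0] - pos[0]))
        add_turn(leg_dir)
        add_walk(act)
        add_turn(act_h)
        t_start = total_time()
        add_stand(script.stop_duration)
        t_end = total_time()
        stops.append(
            dict(
                point_id=pid,
                t_start=t_start,
                t_end=t_end,
                x=wx,
                y=wy,
                heading=wh,
                actual_x=act[0],
                actual_y=act[1],
                actual_heading=wrap_heading(act_h),
            )
        )

    end_dir = math.degrees(math.atan2(script.end[1] - pos[1], script.end[0] - pos[0]))
    add_turn(end_dir)
    add_walk(np.array(script.end))
    add_stand(0.5)

    # sample at the IMU rate
    total = total_time()
    n = int(math.floor(total / dt))
    t = np.arange(n) * dt
    xs = np.empty(n)
    ys = np.empty(n)
    hs = np.empty(n)
    seg_idx = 0
    seg_t0 = 0.0
    for i, ti in enumerate(t):
        while seg_idx < len(segs) - 1 and ti - seg_t0 >= segs[seg_idx][0]:
            seg_t0 += segs[seg_idx][0]
            seg_idx += 1
        xs[i], ys[i], hs[i] = segs[seg_idx][1](ti - seg_t0)

    # smooth to keep velocities/accelerations finite and gait-plausible
    sigma = 0.15 / dt
    xs = gaussian_filter1d(xs, sigma, mode="nearest")
    ys = gaussian_filter1d(ys, sigma, mode="nearest")
    hs = gaussian_filter1d(hs, sigma, mode="nearest")

    return Trajectory(
        t=t, x=xs, y=ys, heading_deg=hs, stops=pd.DataFrame(stops)
    )


# ---------------------------------------------------------------------------
# Inertial simulation


def _mount_rotation(tilt_deg_x: float, tilt_deg_z: float) -> np.ndarray:
    """Small constant device-frame tilt (imperfect belt placement)."""
    ax, az = math.radians(tilt_deg_x), math.radians(tilt_deg_z)
    rx = np.array(
        [[1, 0, 0], [0, math.cos(ax), -math.sin(ax)], [0, math.sin(ax), math.cos(ax)]]
    )
    rz = np.array(
        [[math.cos(az), -math.sin(az), 0], [math.sin(az), math.cos(az), 0], [0, 0, 1]]
    )
    return rx @ rz


def simulate_imu(
    traj: Trajectory,
    config: SimConfig,
    rng: np.random.Generator,
    mount_azimuth_deg: float = 0.0,
    mount_tilt: np.ndarray | None = None,
) -> pd.DataFrame:
    """MARG sample stream for a body trajectory.

    The device is mounted with its x-axis up, y-axis along the wearer's
    dorsoventral (forward) axis rotated by ``mount_azimuth_deg`` clockwise
    (viewed from above) around the body vertical -- the attachment-offset
    convention in which a Method1 heading estimate errs by minus the
    offset -- plus an optional constant tilt. Gravity therefore lies
    along the device's negative x-axis when standing upright.

    Returns a DataFrame with columns t, gx..gz (rad/s), ax..az (m/s^2),
    mx..mz (unit-magnitude field).
    """
    dt = traj.t[1] - traj.t[0]
    h_eff = np.radians(traj.heading_deg - mount_azimuth_deg)
    hd = np.gradient(np.radians(traj.heading_deg), dt)  # rad/s about world z

    vx = np.gradient(traj.x, dt)
    vy = np.gradient(traj.y, dt)
    ax_l = np.gradient(vx, dt)
    ay_l = np.gradient(vy, dt)

    cos_h, sin_h = np.cos(h_eff), np.sin(h_eff)
    f_lab = np.column_stack([ax_l, ay_l, np.full_like(ax_l, G)])

    # device base axes in the lab frame: x_d = up, y_d = forward, z_d = left
    def to_device(v):  # (N, 3) lab -> device (before tilt)
        return np.column_stack(
            [
                v[:, 2],
                v[:, 0] * cos_h + v[:, 1] * sin_h,
                -v[:, 0] * sin_h + v[:, 1] * cos_h,
            ]
        )

    f_dev = to_device(f_lab)
    omega_dev = np.column_stack([hd, np.zeros_like(hd), np.zeros_like(hd)])

    inc = math.radians(config.mag_inclination_deg)
    nu = math.radians(config.north_deg)
    m_lab = np.array(
        [math.cos(inc) * math.cos(nu), math.cos(inc) * math.sin(nu), -math.sin(inc)]
    )
    m_dev = to_device(np.broadcast_to(m_lab, (len(traj.t), 3)).copy())

    if mount_tilt is not None:
        f_dev = f_dev @ mount_tilt
        omega_dev = omega_dev @ mount_tilt
        m_dev = m_dev @ mount_tilt

    n = len(traj.t)
    if config.gyro_bias_std:
        omega_dev = omega_dev + rng.normal(0.0, config.gyro_bias_std, 3)
    if config.gyro_noise:
        omega_dev = omega_dev + rng.normal(0.0, config.gyro_noise, (n, 3))
    if config.accel_noise:
        f_dev = f_dev + rng.normal(0.0, config.accel_noise, (n, 3))
    if config.mag_noise:
        m_dev = m_dev + rng.normal(0.0, config.mag_noise, (n, 3))

    return pd.DataFrame(
        dict(
            t=traj.t,
            gx=omega_dev[:, 0],
            gy=omega_dev[:, 1],
            gz=omega_dev[:, 2],
            ax=f_dev[:, 0],
            ay=f_dev[:, 1],
            az=f_dev[:, 2],
            mx=m_dev[:, 0],
            my=m_dev[:, 1],
            mz=m_dev[:, 2],
        )
    )


# ---------------------------------------------------------------------------
# Depth rendering

_floor_cache: dict = {}


def floor_depth_mm(camera: DepthCamera) -> np.ndarray:
    """Depth raster (mm, uint16) of the empty floor, cached per camera."""
    key = id(camera)
    if key not in _floor_cache:
        dirs = camera.rays_cam.reshape(-1, 3) @ camera.rotation.T  # z-normalized
        dz = dirs[:, 2]
        cz = camera.position[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(dz < 0, -cz / dz, np.inf)
        depth = s * 1000.0
        depth[(depth < 400.0) | (depth > 6000.0) | ~np.isfinite(depth)] = 0.0
        h, w = camera.intrinsics.height, camera.intrinsics.width
        _floor_cache[key] = depth.reshape(h, w).astype(np.uint16)
    return _floor_cache[key]


def render_depth_frame(
    body: BodyModel,
    position,
    heading_deg: float,
    camera: DepthCamera,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    t: float = 0.0,
):
    """Pinhole depth rendering of floor plus body; returns
    ``(depth_mm uint16 HxW, silhouette bool HxW)``.

    Depth noise has standard deviation ``coeff * z^2`` and is applied to
    body pixels; returns beyond 6 m or closer than 0.4 m are invalid (0).
    The silhouette of body pixels is exact ground truth.
    """
    rng = rng or np.random.default_rng()
    floor = floor_depth_mm(camera)
    depth = floor.copy()
    h_img, w_img = depth.shape
    sil = np.zeros((h_img, w_img), dtype=bool)

    pos = np.asarray(position, dtype=float)[:2]
    h_rad = math.radians(heading_deg)
    fwd = np.array([math.cos(h_rad), math.sin(h_rad)])
    left = np.array([-math.sin(h_rad), math.cos(h_rad)])
    a = body.chest_depth / 2.0
    b = body.shoulder_width / 2.0
    head_c = np.array(
        [
            pos[0] + body.head_forward_offset * fwd[0],
            pos[1] + body.head_forward_offset * fwd[1],
            body.height - body.head_radius,
        ]
    )

    # bounding box from projected extreme points
    corners = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            p2 = pos + sx * a * fwd + sy * b * left
            corners.append([p2[0], p2[1], 0.0])
            corners.append([p2[0], p2[1], body.torso_top])
    for d in np.eye(3):
        corners.append(head_c + body.head_radius * d)
        corners.append(head_c - body.head_radius * d)
    col, row, z = camera.project(np.array(corners))
    ok = z > 0.05
    if not ok.any():
        return depth, sil
    pad = 4
    c0 = int(np.floor(col[ok].min())) - pad
    c1 = int(np.ceil(col[ok].max())) + pad
    r0 = int(np.floor(row[ok].min())) - pad
    r1 = int(np.ceil(row[ok].max())) + pad
    c0, c1 = max(c0, 0), min(c1, w_img - 1)
    r0, r1 = max(r0, 0), min(r1, h_img - 1)
    if c1 < c0 or r1 < r0:
        return depth, sil

    rays = camera.rays_cam[r0 : r1 + 1, c0 : c1 + 1].reshape(-1, 3)
    d_w = rays @ camera.rotation.T  # param s = camera-frame depth
    c_w = camera.position

    s_body = np.full(len(d_w), np.inf)

    # torso: elliptical cylinder 0 <= z <= torso_top
    rel = c_w[:2] - pos
    u0 = np.array([rel @ fwd / a, rel @ left / b])
    du = np.column_stack(
        [
            (d_w[:, :2] @ fwd) / a,
            (d_w[:, :2] @ left) / b,
        ]
    )
    qa = np.einsum("ij,ij->i", du, du)
    qb = 2.0 * (du @ u0)
    qc = float(u0 @ u0) - 1.0
    disc = qb * qb - 4.0 * qa * qc
    hit = (disc > 0) & (qa > 0)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    s_cyl = np.where(hit, (-qb - sq) / (2.0 * qa), np.inf)
    z_cyl = c_w[2] + s_cyl * d_w[:, 2]
    valid_cyl = hit & (s_cyl > 0.05) & (z_cyl >= 0.0) & (z_cyl <= body.torso_top)
    s_body = np.where(valid_cyl, s_cyl, s_body)

    # torso top cap (seen from above)
    dz = d_w[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        s_cap = (body.torso_top - c_w[2]) / dz
    u_cap = u0[None, :] + s_cap[:, None] * du
    valid_cap = (s_cap > 0.05) & (np.einsum("ij,ij->i", u_cap, u_cap) <= 1.0)
    s_body = np.minimum(s_body, np.where(valid_cap, s_cap, np.inf))

    # head sphere
    oc = c_w - head_c
    qa_h = np.einsum("ij,ij->i", d_w, d_w)
    qb_h = 2.0 * (d_w @ oc)
    qc_h = float(oc @ oc) - body.head_radius**2
    disc_h = qb_h * qb_h - 4.0 * qa_h * qc_h
    hit_h = disc_h > 0
    sq_h = np.sqrt(np.where(hit_h, disc_h, 0.0))
    s_sph = np.where(hit_h, (-qb_h - sq_h) / (2.0 * qa_h), np.inf)
    valid_sph = hit_h & (s_sph > 0.05)
    s_body = np.minimum(s_body, np.where(valid_sph, s_sph, np.inf))

    patch_floor = floor[r0 : r1 + 1, c0 : c1 + 1].reshape(-1).astype(float)
    floor_s = np.where(patch_floor > 0, patch_floor / 1000.0, np.inf)
    body_px = s_body < floor_s
    if body_px.any():
        s = s_body[body_px]
        if config.depth_noise_coeff:
            s = s + rng.normal(0.0, config.depth_noise_coeff * s**2)
        d_mm = s * 1000.0
        invalid = (d_mm < 400.0) | (d_mm > 6000.0)
        if config.depth_dropout:
            invalid |= rng.random(len(d_mm)) < config.depth_dropout
        d_mm[invalid] = 0.0

        patch = depth[r0 : r1 + 1, c0 : c1 + 1].reshape(-1)
        patch[body_px] = d_mm.astype(np.uint16)
        depth[r0 : r1 + 1, c0 : c1 + 1] = patch.reshape(r1 - r0 + 1, c1 - c0 + 1)

        sil_patch = np.zeros(len(d_w), dtype=bool)
        sil_patch[body_px] = ~invalid
        sil[r0 : r1 + 1, c0 : c1 + 1] = sil_patch.reshape(r1 - r0 + 1, c1 - c0 + 1)
    return depth, sil


# ---------------------------------------------------------------------------
# Whole-experiment generation


@dataclass
class Participant:
    id: int
    body: BodyModel
    mount_azimuth_deg: float  # effective device azimuth offset (CW from above)
    mount_tilt: np.ndarray
    nominal_offset_deg: float  # the condition's mount offset before jitter


@dataclass
class WalkSimulation:
    """One recorded walk: trajectory, IMU stream and on-demand depth
    frames for the active camera."""

    participant: Participant
    condition: str
    walk_name: str
    traj: Trajectory
    imu: pd.DataFrame
    cameras: list
    frames_t: np.ndarray
    frame_x: np.ndarray
    frame_y: np.ndarray
    frame_heading: np.ndarray
    active_camera: np.ndarray  # camera index per frame, -1 when none
    config: SimConfig
    _depth_seed: int = 0

    def n_frames(self) -> int:
        return len(self.frames_t)

    def iter_frames(self):
        """Yield ``(i, t, cam_idx, depth_mm, silhouette)``; cam_idx = -1
        means the person is outside every camera's usable volume and no
        frame is rendered."""
        from .planview import DepthFrame

        rng = np.random.default_rng(self._depth_seed)
        for i, t in enumerate(self.frames_t):
            ci = int(self.active_camera[i])
            if ci < 0:
                yield i, t, -1, None, None
                continue
            depth, sil = render_depth_frame(
                self.participant.body,
                (self.frame_x[i], self.frame_y[i]),
                self.frame_heading[i],
                self.cameras[ci],
                self.config,
                rng,
                t=t,
            )
            yield i, t, ci, DepthFrame(depth=depth, t=t), sil


def _visible_camera(cameras, x, y, half_fov_deg=30.0, d_min=1.8, d_max=6.2):
    """Index of the camera most likely to see a person at (x, y), or -1."""
    best, best_d = -1, np.inf
    for i, cam in enumerate(cameras):
        gx, gy = cam.position[0], cam.position[1]
        fwd = cam.rotation[:, 2][:2]
        fwd = fwd / np.linalg.norm(fwd)
        rel = np.array([x - gx, y - gy])
        d = float(np.linalg.norm(rel))
        if d < d_min or d > d_max:
            continue
        bearing = math.degrees(
            math.acos(np.clip(rel @ fwd / max(d, 1e-9), -1.0, 1.0))
        )
        if bearing > half_fov_deg:
            continue
        if d < best_d:
            best, best_d = i, d
    return best


def _make_participant(pid: int, condition: str, config: SimConfig, rng) -> Participant:
    height = float(rng.normal(config.height_mean, config.height_std))
    body = BodyModel(
        height=height,
        shoulder_width=float(rng.uniform(0.40, 0.48)),
        chest_depth=float(rng.uniform(0.22, 0.30)),
        head_forward_offset=float(rng.uniform(0.03, 0.06)),
    )
    if condition == "position2":
        off = config.mount_offset_deg
        if not isinstance(off, (tuple, list)):
            off = (50.0, 60.0)
        nominal = float(rng.uniform(*off))
    else:
        nominal = (
            float(config.mount_offset_deg)
            if not isinstance(config.mount_offset_deg, (tuple, list))
            else 0.0
        )
        if condition == "position1":
            nominal = 0.0
    azimuth = nominal + (
        float(rng.normal(0.0, config.mount_jitter_deg)) if config.mount_jitter_deg else 0.0
    )
    tilt = _mount_rotation(
        float(rng.normal(0.0, config.mount_tilt_deg)) if config.mount_tilt_deg else 0.0,
        float(rng.normal(0.0, config.mount_tilt_deg)) if config.mount_tilt_deg else 0.0,
    )
    return Participant(
        id=pid,
        body=body,
        mount_azimuth_deg=azimuth,
        mount_tilt=tilt,
        nominal_offset_deg=nominal,
    )


@dataclass
class ExperimentSim:
    config: SimConfig
    condition: str
    cameras: list
    frames: list  # TrackingFrame per camera
    walks: list  # WalkSimulation
    truth: pd.DataFrame


def generate_experiment(
    n_participants: int = 12,
    condition: str = "position1",
    config: SimConfig | None = None,
    seed: int = 0,
) -> ExperimentSim:
    """Simulate the full protocol for one sensor-mount condition.

    Each participant (heights drawn from the cohort's Normal(1.742,
    0.088) m) performs the left-turn walk (points 1-6) and the right-turn
    walk (points 7-12), giving 12 stop events per participant per
    condition. Deterministic per (config, seed).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    config = config or SimConfig()
    cameras, frames = default_rig(config)
    root = np.random.SeedSequence([seed, {"position1": 1, "position2": 2}[condition]])
    walks = []
    truth_rows = []
    for pid, ss in enumerate(root.spawn(n_participants), start=1):
        child = ss.spawn(5)
        prng = np.random.default_rng(child[0])
        participant = _make_participant(pid, condition, config, prng)
        for walk_name, script in (("A", WALK_A), ("B", WALK_B)):
            script = replace(
                script,
                speed=config.walking_speed,
                stop_duration=config.stop_duration,
            )
            wrng = np.random.default_rng(child[1 if walk_name == "A" else 2])
            traj = build_trajectory(script, config, wrng)
            imu = simulate_imu(
                traj,
                config,
                wrng,
                mount_azimuth_deg=participant.mount_azimuth_deg,
                mount_tilt=participant.mount_tilt,
            )
            ft = np.arange(0.0, traj.t[-1], 1.0 / config.fps)
            fx = np.interp(ft, traj.t, traj.x)
            fy = np.interp(ft, traj.t, traj.y)
            fh = np.interp(ft, traj.t, traj.heading_deg)
            active = np.array(
                [_visible_camera(cameras, fx[i], fy[i]) for i in range(len(ft))]
            )
            depth_seed = int(
                np.random.default_rng(child[3]).integers(0, 2**31 - 1)
            ) + (0 if walk_name == "A" else 1)
            walks.append(
                WalkSimulation(
                    participant=participant,
                    condition=condition,
                    walk_name=walk_name,
                    traj=traj,
                    imu=imu,
                    cameras=cameras,
                    frames_t=ft,
                    frame_x=fx,
                    frame_y=fy,
                    frame_heading=fh,
                    active_camera=active,
                    config=config,
                    _depth_seed=depth_seed,
                )
            )
            st = traj.stops.copy()
            st.insert(0, "participant", pid)
            st.insert(1, "condition", condition)
            st.insert(2, "walk", walk_name)
            st["mount_offset_deg"] = participant.nominal_offset_deg
            truth_rows.append(st)
    truth = pd.concat(truth_rows, ignore_index=True)
    return ExperimentSim(
        config=config,
        condition=condition,
        cameras=cameras,
        frames=frames,
        walks=walks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Classifier training data


def generate_template_dataset(
    n_bodies: int = 4,
    n_noise_reps: int = 3,
    config: SimConfig | None = None,
    seed: int = 0,
    camera_index: int = 0,
):
    """Labeled height templates for the 8 principal orientations.

    ``n_bodies`` synthetic people of different heights stand at the 0.5 m
    grid positions inside the chosen camera's usable volume, at each of
    the eight 45-degree headings, rendered ``n_noise_reps`` times with
    fresh depth noise. Returns ``(templates, labels)`` with labels in
    0..7 (class k = heading k * 45 degrees in the camera tracking frame).
    """
    from .classifier import extract_height_template
    from .planview import (
        BackgroundModel,
        DepthFrame,
        TrackerParams,
        build_plan_view_maps,
        subtract_background,
    )

    config = config or SimConfig()
    cameras, frames = default_rig(config)
    cam, frame = cameras[camera_index], frames[camera_index]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))

    heights = [1.60, 1.70, 1.78, 1.88][:n_bodies]
    bodies = [
        BodyModel(
            height=h,
            shoulder_width=float(rng.uniform(0.40, 0.48)),
            chest_depth=float(rng.uniform(0.22, 0.30)),
            head_forward_offset=float(rng.uniform(0.03, 0.06)),
        )
        for h in heights
    ]

    # 0.5 m grid positions inside this camera's usable volume
    positions = []
    for gx in np.arange(0.25, 8.0, 0.5):
        for gy in np.arange(0.25, 5.0, 0.5):
            if _visible_camera([cam], gx, gy, half_fov_deg=24.0, d_min=2.3, d_max=5.2) == 0:
                positions.append((gx, gy))

    bg = BackgroundModel(depth=floor_depth_mm(cam).copy())
    params = TrackerParams()
    cam_yaw = camera_yaw_deg(frame)

    templates, labels = [], []
    for body in bodies:
        for pos in positions:
            for cls in range(8):
                heading_world = wrap_heading(cls * 45.0 + (cam_yaw - 90.0))
                for _ in range(n_noise_reps):
                    depth, sil = render_depth_frame(
                        body, pos, heading_world, cam, config, rng
                    )
                    f = DepthFrame(depth=depth, t=0.0)
                    mask = subtract_background(f, bg, params.tau)
                    if not mask.any():
                        continue
                    pts = frame.to_frame(cam.unproject(depth, mask))
                    maps = build_plan_view_maps(
                        pts, cell=params.cell, cutoff=params.cutoff, bounds=params.bounds
                    )
                    occ = maps.occupancy
                    if occ.sum() < params.min_occupancy:
                        continue
                    ix, iy = np.nonzero(occ)
                    w = occ[ix, iy]
                    cx_, cy_ = maps.cell_center(ix, iy)
                    center = (
                        float(np.average(cx_, weights=w)),
                        float(np.average(cy_, weights=w)),
                    )
                    tpl = extract_height_template(maps, center)
                    if tpl.nonzero_count == 0:
                        continue
                    templates.append(tpl)
                    labels.append(cls)
    return templates, np.array(labels, dtype=int)
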