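"""Plan-view depth tracking: background subtraction, floor-grid feature
maps, and per-person particle filters.

The tracker observes a person as the cloud of foreground depth pixels
projected onto the floor of the camera's tracking frame, summarized per
grid cell as maximum height and point occupancy (and mean color when a
registered color stream exists). A height cut-off around 1 m removes
furniture-level clutter, so only head/shoulder structure drives tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import TrackingFrame

__all__ = [
    "CameraIntrinsics",
    "DepthCamera",
    "DepthFrame",
    "BackgroundModel",
    "PlanViewMaps",
    "PersonTrack",
    "TrackerParams",
    "PlanViewTracker",
    "subtract_background",
    "update_background",
    "build_plan_view_maps",
    "pf_predict",
    "pf_correct",
    "detect_new_persons",
    "estimate_position",
]

DEPTH_MIN_MM = 400
DEPTH_MAX_MM = 6000


@dataclass(frozen=True)
class CameraIntrinsics:
    fx: float = 585.0
    fy: float = 585.0
    cx: float = 319.5
    cy: float = 239.5
    width: int = 640
    height: int = 480


@dataclass(frozen=True)
class DepthFrame:
    """Depth raster in mm (uint16), 0 = invalid, with timestamp and
    intrinsics."""

    depth: np.ndarray
    t: float
    intrinsics: CameraIntrinsics = CameraIntrinsics()

    @property
    def valid(self) -> np.ndarray:
        return self.depth > 0


class DepthCamera:
    """Pinhole depth camera with a rigid pose in the world frame.

    Camera axes follow the computer-vision convention: x right, y down,
    z forward (optical axis). ``rotation`` maps camera coordinates to
    world coordinates; ``position`` is the optical center in world
    coordinates.
    """

    def __init__(
        self,
        position,
        rotation,
        intrinsics: CameraIntrinsics = CameraIntrinsics(),
        max_range_m: float = DEPTH_MAX_MM / 1000.0,
    ):
        self.position = np.asarray(position, dtype=float)
        self.rotation = np.asarray(rotation, dtype=float)
        self.intrinsics = intrinsics
        self.max_range_m = float(max_range_m)
        self._rays_cam = None

    @classmethod
    def from_yaw_pitch(
        cls, position, yaw_deg: float, pitch_deg: float, intrinsics=CameraIntrinsics()
    ) -> "DepthCamera":
        """Camera at ``position`` looking at azimuth ``yaw_deg`` (CCW from
        world x) with the optical axis depressed ``pitch_deg`` below the
        horizontal."""
        yaw = np.radians(yaw_deg)
        pitch = np.radians(pitch_deg)
        z_c = np.array(
            [np.cos(pitch) * np.cos(yaw), np.cos(pitch) * np.sin(yaw), -np.sin(pitch)]
        )
        x_c = np.array([np.sin(yaw), -np.cos(yaw), 0.0])
        y_c = np.cross(z_c, x_c)
        return cls(position, np.column_stack([x_c, y_c, z_c]), intrinsics)

    @property
    def rays_cam(self) -> np.ndarray:
        """(H, W, 3) per-pixel ray directions in camera coordinates with
        unit z (so ``point_cam = depth * ray``)."""
        if self._rays_cam is None:
            ii = self.intrinsics
            u = (np.arange(ii.width) - ii.cx) / ii.fx
            v = (np.arange(ii.height) - ii.cy) / ii.fy
            uu, vv = np.meshgrid(u, v)
            self._rays_cam = np.stack([uu, vv, np.ones_like(uu)], axis=-1)
        return self._rays_cam

    def unproject(self, depth_mm: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """World coordinates of the masked pixels (depth in mm -> m)."""
        z = depth_mm[mask].astype(float) / 1000.0
        rays = self.rays_cam[mask]
        pts_cam = rays * z[:, None]
        return pts_cam @ self.rotation.T + self.position

    def project(self, points_world: np.ndarray):
        """Pixel coordinates (col, row) and depth (m) of world points."""
        pts = (np.atleast_2d(points_world) - self.position) @ self.rotation
        z = pts[:, 2]
        ii = self.intrinsics
        with np.errstate(divide="ignore", invalid="ignore"):
            col = ii.fx * pts[:, 0] / z + ii.cx
            row = ii.fy * pts[:, 1] / z + ii.cy
        return col, row, z


# ---------------------------------------------------------------------------
# Background model


@dataclass
class BackgroundModel:
    """Per-pixel reference depth (mm), refreshed from a median of buffered
    frames only while no tracked person is in view."""

    depth: np.ndarray
    last_update: float = 0.0
    update_period: float = 120.0
    n_frames: int = 5
    _buffer: list = field(default_factory=list, repr=False)

    @classmethod
    def from_frames(cls, frames, **kwargs) -> "BackgroundModel":
        stack = np.stack([f.depth for f in frames]).astype(np.uint16)
        med = np.median(stack, axis=0).astype(np.uint16)
        return cls(depth=med, last_update=frames[-1].t, **kwargs)


def subtract_background(
    frame: DepthFrame, bg: BackgroundModel, tau: float = 0.10
) -> np.ndarray:
    """Foreground mask: pixels with a valid measurement that is closer to
    the camera than the background by more than ``tau`` meters. A valid
    return where the background has none (e.g. the floor behind the
    person is out of range) is also foreground; invalid frame pixels
    never are."""
    if frame.depth.shape != bg.depth.shape:
        raise ValueError("frame/background dimension mismatch")
    tau_mm = tau * 1000.0
    d = frame.depth.astype(np.int32)
    b = bg.depth.astype(np.int32)
    return (d > 0) & ((b == 0) | (d < b - tau_mm))


def update_background(
    bg: BackgroundModel, frame: DepthFrame, active_tracks: int
) -> BackgroundModel:
    """Buffer frames while the scene is empty; once the update period has
    elapsed, replace the background with the median of the buffer."""
    if active_tracks > 0:
        bg._buffer.clear()
        return bg
    bg._buffer.append(frame.depth)
    if len(bg._buffer) > bg.n_frames:
        bg._buffer.pop(0)
    if (
        frame.t - bg.last_update >= bg.update_period
        and len(bg._buffer) >= bg.n_frames
    ):
        bg.depth = np.median(np.stack(bg._buffer), axis=0).astype(np.uint16)
        bg.last_update = frame.t
        bg._buffer.clear()
    return bg


# ---------------------------------------------------------------------------
# Plan-view maps


@dataclass
class PlanViewMaps:
    """Per-cell max height (m), point occupancy (count) and optional mean
    color over a floor grid. Cells are half-open: cell k covers
    ``[x0 + k*cell, x0 + (k+1)*cell)``."""

    cell: float
    x0: float
    y0: float
    height: np.ndarray  # (nx, ny)
    occupancy: np.ndarray  # (nx, ny)
    color: np.ndarray | None = None  # (nx, ny, 3)

    @property
    def shape(self):
        return self.occupancy.shape

    def cell_index(self, x, y):
        ix = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        iy = np.floor((np.asarray(y) - self.y0) / self.cell).astype(int)
        return ix, iy

    def cell_center(self, ix, iy):
        return (
            self.x0 + (np.asarray(ix) + 0.5) * self.cell,
            self.y0 + (np.asarray(iy) + 0.5) * self.cell,
        )

    def in_bounds(self, ix, iy):
        nx, ny = self.shape
        return (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)


def build_plan_view_maps(
    points,
    colors=None,
    cell: float = 0.05,
    cutoff: float = 1.0,
    bounds=(-3.5, 3.5, 0.0, 6.5),
) -> PlanViewMaps:
    """Accumulate foreground points (tracking-frame x, y, height) into
    plan-view maps; points below the height cut-off are discarded.

    Occupancy conservation: the occupancy total equals the number of
    surviving in-bounds points.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x0, x1, y0, y1 = bounds
    nx = int(np.ceil((x1 - x0) / cell))
    ny = int(np.ceil((y1 - y0) / cell))
    height = np.zeros((nx, ny))
    occupancy = np.zeros((nx, ny))
    color_map = None

    if len(points) and points.shape[1] == 3:
        keep = points[:, 2] >= cutoff
        pts = points[keep]
        if colors is not None:
            colors = np.asarray(colors, dtype=float)[keep]
        if len(pts):
            ix = np.floor((pts[:, 0] - x0) / cell).astype(int)
            iy = np.floor((pts[:, 1] - y0) / cell).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            ix, iy, h = ix[ok], iy[ok], pts[ok, 2]
            flat = ix * ny + iy
            np.add.at(occupancy.ravel(), flat, 1.0)
            np.maximum.at(height.ravel(), flat, h)
            if colors is not None:
                color_map = np.zeros((nx, ny, 3))
                for c in range(3):
                    np.add.at(color_map[:, :, c].ravel(), flat, colors[ok, c])
                nzero = occupancy > 0
                color_map[nzero] /= occupancy[nzero][:, None]
    return PlanViewMaps(
        cell=cell, x0=x0, y0=y0, height=height, occupancy=occupancy, color=color_map
    )


# ---------------------------------------------------------------------------
# Particle filter


@dataclass
class PersonTrack:
    """One person's particle set over (x, y, vx, vy) with normalized
    weights."""

    id: int
    particles: np.ndarray  # (N, 4)
    weights: np.ndarray  # (N,)
    status: str = "tentative"  # tentative | confirmed | lost
    expected_height: float | None = None
    hits: int = 0
    misses: int = 0
    color_model: np.ndarray | None = None


def pf_predict(
    track: PersonTrack,
    dt: float,
    q_pos: float = 0.03,
    q_vel: float = 0.25,
    rng: np.random.Generator | None = None,
) -> PersonTrack:
    """First-order linear (constant-velocity) prediction with additive
    Gaussian noise; weights are untouched."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = rng or np.random.default_rng()
    p = track.particles.copy()
    n = len(p)
    p[:, 0] += p[:, 2] * dt + rng.normal(0.0, q_pos, n)
    p[:, 1] += p[:, 3] * dt + rng.normal(0.0, q_pos, n)
    p[:, 2] += rng.normal(0.0, q_vel, n)
    p[:, 3] += rng.normal(0.0, q_vel, n)
    return replace(track, particles=p, weights=track.weights.copy())


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions, side="left").clip(0, n - 1)


def observation_likelihood(
    maps: PlanViewMaps,
    xy: np.ndarray,
    expected_height: float | None,
    weights=(0.5, 0.3, 0.2),
    smooth_sigma_m: float = 0.10,
    height_sigma_m: float = 0.15,
    floor: float = 1e-4,
    color_model=None,
    _cache: dict | None = None,
) -> np.ndarray:
    """Gaussian-mixture observation support evaluated at 2D points.

    The likelihood is a weighted sum of (a) Gaussian-kernel-smoothed
    occupancy (normalized to peak 1), (b) a height-plausibility kernel
    around the person's expected height and (c) a color-match score when
    both a color map and a track color model exist; a small floor keeps
    out-of-grid particles alive.
    """
    w_occ, w_h, w_col = weights
    if _cache is not None and "occ_smooth" in _cache:
        occ = _cache["occ_smooth"]
    else:
        occ = ndimage.gaussian_filter(maps.occupancy, smooth_sigma_m / maps.cell)
        peak = occ.max()
        if peak > 0:
            occ = occ / peak
        if _cache is not None:
            _cache["occ_smooth"] = occ
    xy = np.atleast_2d(xy)
    ix, iy = maps.cell_index(xy[:, 0], xy[:, 1])
    ok = maps.in_bounds(ix, iy)
    lik = np.full(len(xy), floor)
    if not ok.any():
        return lik
    occ_s = occ[ix[ok], iy[ok]]
    score = w_occ * occ_s
    if expected_height is not None:
        h = maps.height[ix[ok], iy[ok]]
        h_s = np.where(
            h > 0, np.exp(-0.5 * ((h - expected_height) / height_sigma_m) ** 2), 0.0
        )
        score = score + w_h * h_s
    if color_model is not None and maps.color is not None:
        c = maps.color[ix[ok], iy[ok]]
        dist = np.linalg.norm(c - color_model, axis=-1)
        score = score + w_col * np.exp(-0.5 * (dist / 0.25) ** 2)
    lik[ok] = score + floor
    return lik


def pf_correct(
    track: PersonTrack,
    maps: PlanViewMaps,
    rng: np.random.Generator | None = None,
    mixture_weights=(0.5, 0.3, 0.2),
    **lik_kwargs,
) -> PersonTrack:
    """Reweight particles by the plan-view observation support, renormalize
    and resample (systematic) when the effective sample size drops below
    N/2. All-zero support resets the weights uniform and counts a miss."""
    rng = rng or np.random.default_rng()
    lik = observation_likelihood(
        maps,
        track.particles[:, :2],
        track.expected_height,
        weights=mixture_weights,
        color_model=track.color_model,
        **lik_kwargs,
    )
    w = track.weights * lik
    total = w.sum()
    n = len(w)
    if total <= 0 or not np.isfinite(total):
        return replace(
            track, weights=np.full(n, 1.0 / n), misses=track.misses + 1
        )
    w = w / total
    ess = 1.0 / np.sum(w**2)
    particles = track.particles
    if ess < n / 2:
        idx = _systematic_resample(w, rng)
        particles = particles[idx].copy()
        w = np.full(n, 1.0 / n)
    return replace(track, particles=particles, weights=w)


def detect_new_persons(
    maps: PlanViewMaps,
    tracks,
    min_occupancy: float = 50.0,
    min_height: float = 1.3,
    exclusion_radius: float = 0.5,
):
    """Seed positions for new tentative tracks: occupancy-weighted
    centroids of connected components that look person-sized and are not
    already claimed by an existing track."""
    occupied = maps.occupancy > 0
    if not occupied.any():
        return []
    labels, n_comp = ndimage.label(occupied, structure=np.ones((3, 3)))
    seeds = []
    existing = [estimate_position(t) for t in tracks if t.status != "lost"]
    for comp in range(1, n_comp + 1):
        sel = labels == comp
        occ_total = maps.occupancy[sel].sum()
        if occ_total < min_occupancy or maps.height[sel].max() < min_height:
            continue
        ix, iy = np.nonzero(sel)
        w = maps.occupancy[sel]
        cx, cy = maps.cell_center(ix, iy)
        x = float(np.average(cx, weights=w))
        y = float(np.average(cy, weights=w))
        if any(np.hypot(x - ex, y - ey) < exclusion_radius for ex, ey in existing):
            continue
        seeds.append((x, y))
    return seeds


def estimate_position(track: PersonTrack):
    """Posterior mean position (weighted mean of particles)."""
    w = track.weights
    return (
        float(w @ track.particles[:, 0]),
        float(w @ track.particles[:, 1]),
    )


# ---------------------------------------------------------------------------
# Per-camera tracker


@dataclass
class TrackerParams:
    cell: float = 0.05
    cutoff: float = 1.0
    tau: float = 0.10
    n_particles: int = 300
    q_pos: float = 0.03
    q_vel: float = 0.25
    mixture_weights: tuple = (0.5, 0.3, 0.2)
    min_occupancy: float = 50.0
    min_height: float = 1.3
    exclusion_radius: float = 0.5
    confirm_hits: int = 3
    lost_misses: int = 10
    support_radius: float = 0.4
    min_support: float = 10.0
    bounds: tuple = (-3.5, 3.5, 0.0, 6.5)


class PlanViewTracker:
    """Single-camera plan-view tracker: background subtraction, map
    construction and one particle filter per person."""

    def __init__(
        self,
        camera: DepthCamera,
        frame: TrackingFrame,
        params: TrackerParams = TrackerParams(),
        seed: int | np.random.Generator = 0,
    ):
        self.camera = camera
        self.frame = frame
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.background: BackgroundModel | None = None
        self.tracks: list[PersonTrack] = []
        self._next_id = 0
        self._last_t: float | None = None
        self.maps: PlanViewMaps | None = None

    def initialize_background(self, frames):
        self.background = BackgroundModel.from_frames(frames)

    def _new_track(self, x, y, expected_height):
        n = self.params.n_particles
        particles = np.column_stack(
            [
                self.rng.normal(x, 0.1, n),
                self.rng.normal(y, 0.1, n),
                self.rng.normal(0.0, 0.3, n),
                self.rng.normal(0.0, 0.3, n),
            ]
        )
        track = PersonTrack(
            id=self._next_id,
            particles=particles,
            weights=np.full(n, 1.0 / n),
            expected_height=expected_height,
        )
        self._next_id += 1
        return track

    def step(self, depth_frame: DepthFrame):
        """Process one frame; returns the updated list of tracks."""
        if self.background is None:
            raise RuntimeError("background model not initialized")
        p = self.params
        mask = subtract_background(depth_frame, self.background, p.tau)
        # gate the depth range before projecting
        mask &= (depth_frame.depth >= DEPTH_MIN_MM) & (
            depth_frame.depth <= DEPTH_MAX_MM
        )
        if mask.any():
            pts_world = self.camera.unproject(depth_frame.depth, mask)
            pts = self.frame.to_frame(pts_world)
        else:
            pts = np.empty((0, 3))
        maps = build_plan_view_maps(
            pts, cell=p.cell, cutoff=p.cutoff, bounds=p.bounds
        )
        self.maps = maps
        cache: dict = {}

        dt = (
            depth_frame.t - self._last_t
            if self._last_t is not None and depth_frame.t > self._last_t
            else 1.0 / 30.0
        )
        self._last_t = depth_frame.t

        updated = []
        for track in self.tracks:
            track = pf_predict(track, dt, p.q_pos, p.q_vel, self.rng)
            track = pf_correct(
                track,
                maps,
                self.rng,
                mixture_weights=p.mixture_weights,
                _cache=cache,
            )
            x, y = estimate_position(track)
            ix, iy = maps.cell_index(x, y)
            r = int(np.ceil(p.support_radius / p.cell))
            nx, ny = maps.shape
            sl = (
                slice(max(ix - r, 0), min(ix + r + 1, nx)),
                slice(max(iy - r, 0), min(iy + r + 1, ny)),
            )
            support = maps.occupancy[sl].sum() if maps.in_bounds(ix, iy) else 0.0
            if support >= p.min_support:
                track = replace(track, hits=track.hits + 1, misses=0)
                if track.status == "tentative" and track.hits >= p.confirm_hits:
                    track = replace(track, status="confirmed")
            else:
                track = replace(track, misses=track.misses + 1, hits=0)
                if track.misses >= p.lost_misses:
                    track = replace(track, status="lost")
            if track.status != "lost":
                updated.append(track)
        self.tracks = updated

        for x, y in detect_new_persons(
            maps,
            self.tracks,
            p.min_occupancy,
            p.min_height,
            p.exclusion_radius,
        ):
            ix, iy = maps.cell_index(x, y)
            h = maps.height[ix, iy] if maps.in_bounds(ix, iy) else None
            r = int(np.ceil(0.3 / p.cell))
            nx, ny = maps.shape
            patch = maps.height[
                max(ix - r, 0) : min(ix + r + 1, nx),
                max(iy - r, 0) : min(iy + r + 1, ny),
            ]
            h = float(patch.max()) if patch.size else None
            self.tracks.append(self._new_track(x, y, h))

        self.background = update_background(
            self.background,
            depth_frame,
            sum(t.status == "confirmed" for t in self.tracks),
        )
        return self.tracks
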