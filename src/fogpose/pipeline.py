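"""End-to-end pose pipeline: depth tracking for position, inertial (and
vision-fused) heading, stop segmentation and the accuracy tables.

The pipeline is a pure function of its inputs, configuration and seed.
Headings are carried in the world frame of the walking area; a camera's
tracking-frame heading converts to the world frame by adding the camera
yaw minus 90 degrees (the tracking y-axis is the camera forward). With
Method2 the correction angle is latched in the world frame, so a
reference confirmed under one camera remains valid after a hand-off to
the other camera.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from .classifier import (
    HeadingClassifierModel,
    StaticHeadingTracker,
    classify,
    extract_height_template,
    train_classifier,
)
from .fusion import Method2Fusion, dynamic_heading, method1_heading
from .geometry import wrap_heading
from .imu import heading_series, run_filter
from .planview import (
    BackgroundModel,
    PlanViewTracker,
    TrackerParams,
    estimate_position,
)
from .simulate import (
    ExperimentSim,
    SimConfig,
    WalkSimulation,
    camera_yaw_deg,
    floor_depth_mm,
    generate_experiment,
    generate_template_dataset,
)

__all__ = [
    "PipelineConfig",
    "run_pose_pipeline",
    "run_experiment_replication",
    "train_default_classifier",
    "method1_headings_for_walk",
]


@dataclass
class PipelineConfig:
    """Effective configuration of a replication run (serialized alongside
    outputs so every run is reproducible)."""

    sim: SimConfig = field(default_factory=SimConfig)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    method: str = "both"  # method1 | method2 | both
    groe_beta: float = 0.1
    aoe_beta: float = 0.041
    aoe_warmup_s: float = 2.0
    dynamic_window_s: float = 0.5
    min_speed: float = 0.3
    confirm_bound_deg: float = 15.0
    confirm_frames: int = 3
    quality_threshold: float = 0.8
    static_frames: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _interp_heading(t_query, t_src, heading_deg):
    """Interpolate a wrapped heading series (deg) at query times."""
    h = np.asarray(heading_deg, dtype=float)
    good = np.isfinite(h)
    if good.sum() < 2:
        return np.full(len(t_query), np.nan)
    unwrapped = np.degrees(np.unwrap(np.radians(h[good])))
    out = np.interp(t_query, np.asarray(t_src)[good], unwrapped)
    return np.mod(out, 360.0)


def method1_headings_for_walk(
    walk: WalkSimulation, psi_deg: float, camera_yaw: float = 90.0, beta: float = 0.041
):
    """AOE filter over the walk's MARG stream plus the static frame
    corrections; returns (t, theta_world_deg)."""
    imu = walk.imu
    quats = run_filter(
        imu["t"].to_numpy(),
        imu[["gx", "gy", "gz"]].to_numpy(),
        imu[["ax", "ay", "az"]].to_numpy(),
        imu[["mx", "my", "mz"]].to_numpy(),
        mode="aoe",
        beta=beta,
    )
    alpha = heading_series(quats)  # deg CCW from magnetic North
    theta_cam = np.mod(alpha - psi_deg + 90.0, 360.0)
    theta_world = np.mod(theta_cam + (camera_yaw - 90.0), 360.0)
    return imu["t"].to_numpy(), theta_world


def run_pose_pipeline(
    walk: WalkSimulation,
    frames,
    model: HeadingClassifierModel | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Track one walk end to end.

    Returns a per-frame DataFrame: t, x, y (world; NaN while untracked),
    theta_m1, theta_m2 (deg world; NaN where the method's heading is
    undefined or withheld), camera, static quality diagnostics.
    """
    cameras = walk.cameras
    cam_yaws = [camera_yaw_deg(f) for f in frames]
    imu_t = walk.imu["t"].to_numpy()

    want_m1 = config.method in ("method1", "both")
    want_m2 = config.method in ("method2", "both")

    theta_m1_series = None
    if want_m1:
        t_m1, th_m1 = method1_headings_for_walk(
            walk, frames[0].psi_deg, cam_yaws[0], beta=config.aoe_beta
        )
        warm = t_m1 >= config.aoe_warmup_s
        theta_m1_series = (t_m1[warm], th_m1[warm])

    theta_i_series = None
    if want_m2:
        quats = run_filter(
            imu_t,
            walk.imu[["gx", "gy", "gz"]].to_numpy(),
            walk.imu[["ax", "ay", "az"]].to_numpy(),
            mode="groe",
            beta=config.groe_beta,
        )
        theta_i = heading_series(quats)  # arbitrary yaw gauge
        theta_i_series = (imu_t, theta_i)

    trackers = []
    for cam, frame in zip(cameras, frames):
        tr = PlanViewTracker(
            cam, frame, config.tracker, seed=np.random.SeedSequence([config.seed, 11])
        )
        bg = floor_depth_mm(cam)
        tr.background = BackgroundModel(depth=bg.copy())
        trackers.append(tr)

    static_tracker = StaticHeadingTracker(
        config.quality_threshold, config.static_frames
    )
    fusion = Method2Fusion(config.confirm_bound_deg, config.confirm_frames)

    pos_hist_t: list[float] = []
    pos_hist_xy: list[tuple] = []

    rows = []
    last_cam = -1
    for i, t, ci, depth_frame, _sil in walk.iter_frames():
        x = y = np.nan
        static_h = None
        quality = np.nan
        if ci >= 0:
            if ci != last_cam and last_cam >= 0:
                trackers[last_cam].tracks = []  # hand-off: old camera's view ends
                static_tracker.reset()
            last_cam = ci
            tracker = trackers[ci]
            tracks = tracker.step(depth_frame)
            confirmed = [tr for tr in tracks if tr.status == "confirmed"]
            if confirmed:
                best = max(confirmed, key=lambda tr: tr.hits)
                fx, fy = estimate_position(best)
                wx, wy, _ = frames[ci].to_world([(fx, fy, 0.0)])[0]
                x, y = float(wx), float(wy)
                pos_hist_t.append(t)
                pos_hist_xy.append((x, y))
                if model is not None and want_m2 and tracker.maps is not None:
                    tpl = extract_height_template(tracker.maps, (fx, fy))
                    cls, h_cam, quality = classify(model, tpl)
                    sh = static_tracker.update(cls, quality)
                    if sh is not None:
                        static_h = wrap_heading(sh + (cam_yaws[ci] - 90.0))
            else:
                static_tracker.reset()
        else:
            static_tracker.reset()

        dyn_h = None
        if want_m2 and len(pos_hist_t) >= 2:
            tw = np.array(pos_hist_t)
            sel = tw >= t - config.dynamic_window_s
            if sel.sum() >= 3:
                xy = np.array(pos_hist_xy)[sel]
                dyn_h = dynamic_heading(tw[sel], xy[:, 0], xy[:, 1], config.min_speed)

        theta_m2 = np.nan
        if want_m2:
            th_i = _interp_heading([t], *theta_i_series)[0]
            out = fusion.update(t, th_i if np.isfinite(th_i) else None, static_h, dyn_h)
            if out is not None:
                theta_m2 = out

        theta_m1 = np.nan
        if want_m1:
            theta_m1 = _interp_heading([t], *theta_m1_series)[0]

        rows.append(
            dict(
                t=t,
                x=x,
                y=y,
                theta_m1=theta_m1,
                theta_m2=theta_m2,
                camera=ci,
                quality=quality,
            )
        )
    return pd.DataFrame(rows)


def train_default_classifier(
    config: SimConfig | None = None, seed: int = 0, n_noise_reps: int = 2
) -> HeadingClassifierModel:
    """Train the heading classifier on synthetic bodies rendered across
    the camera's field of view (the default model for replication runs)."""
    templates, labels = generate_template_dataset(
        n_bodies=4, n_noise_reps=n_noise_reps, config=config, seed=seed
    )
    return train_classifier(templates, labels, seed=seed)


def run_experiment_replication(
    n_participants: int = 12,
    condition: str = "position1",
    config: PipelineConfig | None = None,
    model: HeadingClassifierModel | None = None,
    sim: ExperimentSim | None = None,
) -> dict:
    """Simulate, track, fuse and evaluate one sensor-mount condition.

    Returns a dict with the truth table, per-frame trajectories, stop
    windows, per-point and per-participant tables and headline metrics.
    """
    config = config or PipelineConfig()
    if sim is None:
        sim = generate_experiment(
            n_participants, condition, config.sim, seed=config.seed
        )
    if model is None and config.method in ("method2", "both"):
        model = train_default_classifier(config.sim, seed=config.seed)

    all_windows = []
    trajs = {}
    for walk in sim.walks:
        traj = run_pose_pipeline(walk, sim.frames, model, config)
        trajs[(walk.participant.id, walk.walk_name)] = traj
        truth_w = sim.truth[
            (sim.truth["participant"] == walk.participant.id)
            & (sim.truth["walk"] == walk.walk_name)
        ]
        win = ev.segment_stops(
            traj, truth_w, heading_columns=("theta_m1", "theta_m2")
        )
        all_windows.append(win)
    windows = pd.concat(all_windows, ignore_index=True)

    out = dict(
        condition=condition,
        truth=sim.truth,
        trajectories=trajs,
        windows=windows,
        position_per_point=ev.position_per_point_stats(windows),
        position_overall=ev.overall_position_rmse(windows),
    )
    for col in ("theta_m1", "theta_m2"):
        pp = ev.per_point_stats(windows, col)
        pr = ev.per_participant_stats(windows, col)
        out[f"{col}_per_point"] = pp
        out[f"{col}_per_participant"] = pr
        if len(pp):
            out[f"{col}_max_point_rmse"] = float(pp["rmse"].max())
        if len(pr):
            out[f"{col}_max_participant_rmse"] = float(pr["rmse"].max())
    return out
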