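import numpy as np
import pytest
from scipy import ndimage

from fogpose.planview import (
    BackgroundModel,
    DepthFrame,
    PersonTrack,
    PlanViewTracker,
    build_plan_view_maps,
    detect_new_persons,
    estimate_position,
    observation_likelihood,
    pf_correct,
    pf_predict,
    subtract_background,
    update_background,
)
from fogpose.simulate import SimConfig, default_rig, floor_depth_mm, render_depth_frame
from fogpose.simulate import BodyModel


@pytest.fixture(scope="module")
def scene():
    """One rendered person in front of camera 1 plus the empty-floor
    background."""
    cfg = SimConfig()
    cams, frames = default_rig(cfg)
    cam, frame = cams[0], frames[0]
    rng = np.random.default_rng(2)
    depth, sil = render_depth_frame(
        BodyModel(height=1.75), (2.25, 1.75), 270.0, cam, cfg, rng
    )
    bg = BackgroundModel(depth=floor_depth_mm(cam).copy())
    return dict(cfg=cfg, cam=cam, frame=frame, depth=depth, sil=sil, bg=bg)


# ---------------------------------------------------------------------------
# Background subtraction


class TestBackgroundSubtraction:
    def test_identical_frame_gives_empty_mask(self, scene):
        f = DepthFrame(depth=scene["bg"].depth.copy(), t=0.0)
        assert not subtract_background(f, scene["bg"]).any()

    def test_person_mask_matches_silhouette(self, scene):
        f = DepthFrame(depth=scene["depth"], t=0.0)
        mask = subtract_background(f, scene["bg"], tau=0.10)
        inter = (mask & scene["sil"]).sum()
        union = (mask | scene["sil"]).sum()
        assert inter / union >= 0.9

    def test_invalid_pixels_never_foreground(self, scene):
        d = scene["depth"].copy()
        d[:, :] = 0
        f = DepthFrame(depth=d, t=0.0)
        assert not subtract_background(f, scene["bg"]).any()

    def test_dimension_mismatch_raises(self, scene):
        f = DepthFrame(depth=np.zeros((10, 10), dtype=np.uint16), t=0.0)
        with pytest.raises(ValueError):
            subtract_background(f, scene["bg"])


class TestBackgroundUpdate:
    def test_gated_by_active_tracks(self):
        base = np.full((4, 4), 3000, dtype=np.uint16)
        bg = BackgroundModel(depth=base.copy(), update_period=10.0, n_frames=3)
        newer = DepthFrame(depth=np.full((4, 4), 2000, dtype=np.uint16), t=100.0)
        update_background(bg, newer, active_tracks=1)
        np.testing.assert_array_equal(bg.depth, base)

    def test_median_replacement_after_period(self):
        bg = BackgroundModel(
            depth=np.full((4, 4), 3000, dtype=np.uint16),
            update_period=10.0,
            n_frames=3,
        )
        vals = [2000, 2100, 2050]
        for i, v in enumerate(vals):
            update_background(
                bg,
                DepthFrame(depth=np.full((4, 4), v, dtype=np.uint16), t=20.0 + i),
                active_tracks=0,
            )
        assert bg.depth[0, 0] == np.median(vals)

    def test_static_scene_converges_to_empty_mask(self, scene):
        """Feeding the same static scene repeatedly makes subtraction of
        that scene empty after an update cycle."""
        frame = DepthFrame(depth=scene["depth"], t=200.0)
        bg = BackgroundModel(
            depth=scene["bg"].depth.copy(), update_period=1.0, n_frames=3
        )
        for i in range(3):
            update_background(
                bg, DepthFrame(depth=scene["depth"], t=200.0 + i), active_tracks=0
            )
        assert not subtract_background(frame, bg).any()


# ---------------------------------------------------------------------------
# Plan-view maps


class TestPlanViewMaps:
    def test_single_point(self):
        maps = build_plan_view_maps(
            [[1.00, 2.00, 1.70]], cell=0.05, cutoff=1.0, bounds=(0, 3, 0, 3)
        )
        assert (maps.occupancy > 0).sum() == 1
        ix, iy = maps.cell_index(1.00, 2.00)
        assert maps.occupancy[ix, iy] == 1
        assert maps.height[ix, iy] == pytest.approx(1.70)

    def test_cutoff_discards_low_points(self):
        """Points at 0.8 m with a 1.0 m cut-off leave the maps empty."""
        pts = np.column_stack(
            [np.random.default_rng(0).uniform(0, 3, (50, 2)), np.full(50, 0.8)]
        )
        maps = build_plan_view_maps(pts, cutoff=1.0, bounds=(0, 3, 0, 3))
        assert maps.occupancy.sum() == 0
        assert maps.height.max() == 0

    def test_occupancy_conservation(self, rng):
        """Occupancy total equals the number of surviving in-bounds
        points, for random clouds."""
        for _ in range(10):
            n = rng.integers(1, 500)
            pts = np.column_stack(
                [rng.uniform(-1, 4, (n, 2)), rng.uniform(0, 2, n)]
            )
            maps = build_plan_view_maps(pts, cutoff=1.0, bounds=(0, 3, 0, 3))
            surviving = (
                (pts[:, 2] >= 1.0)
                & (pts[:, 0] >= 0)
                & (pts[:, 0] < 3.0 - 1e-12)
                & (pts[:, 1] >= 0)
                & (pts[:, 1] < 3.0 - 1e-12)
            ).sum()
            assert maps.occupancy.sum() == pytest.approx(surviving)

    def test_bad_cell_size_raises(self):
        with pytest.raises(ValueError):
            build_plan_view_maps([[0, 0, 1.5]], cell=0.0)

    def test_person_centroid_near_torso_axis(self, scene):
        f = DepthFrame(depth=scene["depth"], t=0.0)
        mask = subtract_background(f, scene["bg"], tau=0.10)
        pts = scene["frame"].to_frame(scene["cam"].unproject(scene["depth"], mask))
        maps = build_plan_view_maps(pts, cell=0.05, cutoff=1.0)
        ix, iy = np.nonzero(maps.occupancy)
        w = maps.occupancy[ix, iy]
        cx, cy = maps.cell_center(ix, iy)
        # true torso floor point in this camera's frame: (0, 2.45)
        got = np.array([np.average(cx, weights=w), np.average(cy, weights=w)])
        assert np.linalg.norm(got - [0.0, 2.45]) < 0.15


# ---------------------------------------------------------------------------
# Particle filter


def _track_at(x, y, n=200, spread=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    particles = np.column_stack(
        [
            rng.normal(x, spread, n) if spread else np.full(n, float(x)),
            rng.normal(y, spread, n) if spread else np.full(n, float(y)),
            np.zeros(n),
            np.zeros(n),
        ]
    )
    return PersonTrack(
        id=0, particles=particles, weights=np.full(n, 1.0 / n), expected_height=1.7
    )


class TestPredict:
    def test_zero_noise_advances_by_velocity(self):
        track = _track_at(0, 0)
        track.particles[:, 2] = 1.0  # vx
        out = pf_predict(track, dt=1 / 30, q_pos=0.0, q_vel=0.0)
        assert out.particles[:, 0].mean() == pytest.approx(1 / 30)

    def test_noise_grows_position_variance(self):
        track = _track_at(0, 0, n=20000)
        out = pf_predict(
            track, dt=1.0, q_pos=0.05, q_vel=0.0, rng=np.random.default_rng(3)
        )
        assert out.particles[:, 0].var() == pytest.approx(0.05**2, rel=0.1)

    def test_weights_unchanged(self, rng):
        track = _track_at(1, 2, rng=rng)
        track.weights[:] = rng.dirichlet(np.ones(len(track.weights)))
        out = pf_predict(track, dt=0.1, rng=rng)
        np.testing.assert_array_equal(out.weights, track.weights)

    def test_bad_dt_raises(self):
        with pytest.raises(ValueError):
            pf_predict(_track_at(0, 0), dt=0.0)


def _maps_with_blob(center, bounds=(0, 1, 0, 1), cell=0.05, height=1.7, count=80):
    maps = build_plan_view_maps(
        np.tile([center[0], center[1], height], (count, 1)),
        cell=cell,
        cutoff=1.0,
        bounds=bounds,
    )
    return maps


class TestCorrect:
    def test_uniform_maps_leave_weights_uniform(self):
        """With spatially constant observation support the posterior
        equals the prior after renormalization."""
        pts = []
        for x in np.arange(0.025, 1.0, 0.05):
            for y in np.arange(0.025, 1.0, 0.05):
                pts.append([x, y, 1.7])
        maps = build_plan_view_maps(pts, cell=0.05, cutoff=1.0, bounds=(0, 1, 0, 1))
        track = _track_at(0.5, 0.5, spread=0.1, rng=np.random.default_rng(1))
        out = pf_correct(track, maps, rng=np.random.default_rng(2))
        np.testing.assert_allclose(out.weights, track.weights, rtol=1e-6)

    def test_concentrated_occupancy_pulls_posterior(self):
        """Occupancy in one cell with diffuse particles: posterior mean
        lands within one cell of that cell center (checked against a
        dense-grid Bayes filter below as well)."""
        maps = _maps_with_blob((0.525, 0.525))
        track = _track_at(0.5, 0.5, n=4000, spread=0.15, rng=np.random.default_rng(4))
        out = pf_correct(track, maps, rng=np.random.default_rng(5))
        x, y = estimate_position(out)
        assert abs(x - 0.525) < 0.05 and abs(y - 0.525) < 0.05

    def test_two_blobs_prior_disambiguates(self):
        """Two equal blobs; prior centered on one: posterior mass > 0.8
        near the closer blob."""
        pts = np.vstack(
            [
                np.tile([0.3, 0.5, 1.7], (60, 1)),
                np.tile([0.7, 0.5, 1.7], (60, 1)),
            ]
        )
        maps = build_plan_view_maps(pts, cell=0.05, cutoff=1.0, bounds=(0, 1, 0, 1))
        track = _track_at(0.3, 0.5, n=4000, spread=0.08, rng=np.random.default_rng(6))
        out = pf_correct(track, maps, rng=np.random.default_rng(7))
        near = np.hypot(
            out.particles[:, 0] - 0.3, out.particles[:, 1] - 0.5
        ) < np.hypot(out.particles[:, 0] - 0.7, out.particles[:, 1] - 0.5)
        assert out.weights[near].sum() > 0.8

    def test_all_zero_support_resets_uniform_and_flags(self):
        maps = build_plan_view_maps(
            np.empty((0, 3)), cell=0.05, cutoff=1.0, bounds=(0, 1, 0, 1)
        )
        track = _track_at(5.0, 5.0, spread=0.01)  # far out of grid
        out = pf_correct(track, maps, rng=np.random.default_rng(0), floor=0.0)
        np.testing.assert_allclose(out.weights, 1.0 / len(out.weights))
        assert out.misses == track.misses + 1


class TestGridFilterEquivalence:
    def _grid_bayes_filter(self, maps, prior_mu, steps, dt, q_pos, expected_height):
        """Independent dense-grid Bayesian filter on the map's grid: the
        same Gaussian random-walk motion and the same observation
        likelihood field, computed by explicit convolution."""
        nx, ny = maps.shape
        xs = maps.x0 + (np.arange(nx) + 0.5) * maps.cell
        ys = maps.y0 + (np.arange(ny) + 0.5) * maps.cell
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        p = np.exp(
            -0.5 * ((gx - prior_mu[0]) ** 2 + (gy - prior_mu[1]) ** 2) / 0.15**2
        )
        p /= p.sum()
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        lik = observation_likelihood(maps, centers, expected_height).reshape(nx, ny)
        for _ in range(steps):
            p = ndimage.gaussian_filter(p, q_pos / maps.cell, mode="constant")
            p = p * lik
            p /= p.sum()
        return float((p * gx).sum()), float((p * gy).sum())

    def test_pf_matches_dense_grid_filter(self):
        """Particle-filter posterior mean stays within 1.5 cells of the
        dense-grid filter on a small scene."""
        maps = _maps_with_blob((0.575, 0.425))
        dt, q_pos, steps = 1 / 15, 0.03, 8
        rng = np.random.default_rng(11)
        track = _track_at(0.45, 0.55, n=5000, spread=0.12, rng=rng)
        for _ in range(steps):
            track = pf_predict(track, dt, q_pos=q_pos, q_vel=0.0, rng=rng)
            track = pf_correct(track, maps, rng=rng)
        px, py = estimate_position(track)
        ox, oy = self._grid_bayes_filter(maps, (0.45, 0.55), steps, dt, q_pos, 1.7)
        assert np.hypot(px - ox, py - oy) < 1.5 * maps.cell


class TestDetection:
    def test_empty_maps_no_seeds(self):
        maps = build_plan_view_maps(
            np.empty((0, 3)), cell=0.05, cutoff=1.0, bounds=(0, 3, 0, 3)
        )
        assert detect_new_persons(maps, []) == []

    def test_single_person_single_seed(self, scene):
        f = DepthFrame(depth=scene["depth"], t=0.0)
        mask = subtract_background(f, scene["bg"], tau=0.10)
        pts = scene["frame"].to_frame(scene["cam"].unproject(scene["depth"], mask))
        maps = build_plan_view_maps(pts, cell=0.05, cutoff=1.0)
        seeds = detect_new_persons(maps, [])
        assert len(seeds) == 1
        assert np.hypot(seeds[0][0] - 0.0, seeds[0][1] - 2.45) < 0.2

    def test_existing_track_suppresses_seed(self, scene):
        f = DepthFrame(depth=scene["depth"], t=0.0)
        mask = subtract_background(f, scene["bg"], tau=0.10)
        pts = scene["frame"].to_frame(scene["cam"].unproject(scene["depth"], mask))
        maps = build_plan_view_maps(pts, cell=0.05, cutoff=1.0)
        track = _track_at(0.0, 2.45)
        assert detect_new_persons(maps, [track]) == []


class TestEstimatePosition:
    def test_examples(self):
        track = _track_at(0, 0, n=2)
        track.particles[0, :2] = [0, 0]
        track.particles[1, :2] = [2, 0]
        track.weights[:] = 0.5
        assert estimate_position(track) == pytest.approx((1.0, 0.0))
        track.weights[:] = [1.0, 0.0]
        assert estimate_position(track) == pytest.approx((0.0, 0.0))

    def test_matches_hand_sum(self, rng):
        track = _track_at(0, 0, n=50)
        track.particles[:, :2] = rng.normal(size=(50, 2))
        w = rng.dirichlet(np.ones(50))
        track.weights[:] = w
        x, y = estimate_position(track)
        assert x == pytest.approx(sum(w[i] * track.particles[i, 0] for i in range(50)), abs=1e-12)
        assert y == pytest.approx(sum(w[i] * track.particles[i, 1] for i in range(50)), abs=1e-12)


# ---------------------------------------------------------------------------
# End-to-end tracker properties


class TestTrackerEndToEnd:
    @pytest.mark.parametrize("pos,truth_frame", [
        ((2.25, 1.75), (0.0, 2.45)),
        ((3.25, 4.25), (1.0, 4.95)),
    ])
    def test_stationary_person_rmse(self, pos, truth_frame):
        """A stationary upright person in the 1-6 m range is tracked with
        per-coordinate RMSE below 0.16 m over a 1 s window."""
        cfg = SimConfig()
        cams, frames = default_rig(cfg)
        cam, frame = cams[0], frames[0]
        rng = np.random.default_rng(9)
        tracker = PlanViewTracker(cam, frame, seed=10)
        tracker.background = BackgroundModel(depth=floor_depth_mm(cam).copy())
        body = BodyModel(height=1.74)
        est = []
        for i in range(30):  # 2 s at 15 Hz; evaluate the final 1 s
            depth, _ = render_depth_frame(body, pos, 270.0, cam, cfg, rng)
            tracks = tracker.step(DepthFrame(depth=depth, t=i / 15))
            confirmed = [t for t in tracks if t.status == "confirmed"]
            if confirmed:
                est.append(estimate_position(confirmed[0]))
        assert len(est) >= 15
        est = np.array(est[-15:])
        err = est - np.array(truth_frame)
        assert np.sqrt(np.mean(err[:, 0] ** 2)) <= 0.16
        assert np.sqrt(np.mean(err[:, 1] ** 2)) <= 0.16

    def test_below_cutoff_clutter_is_invisible(self):
        """Clutter entirely below the 1.0 m cut-off does not change the
        tracked trajectory."""
        cfg = SimConfig()
        cams, frames = default_rig(cfg)
        cam, frame = cams[0], frames[0]
        body = BodyModel(height=1.74)

        def run(with_clutter):
            rng = np.random.default_rng(21)
            clutter_rng = np.random.default_rng(22)
            tracker = PlanViewTracker(cam, frame, seed=23)
            tracker.background = BackgroundModel(depth=floor_depth_mm(cam).copy())
            est = []
            for i in range(20):
                depth, _ = render_depth_frame(body, (2.25, 1.75), 0.0, cam, cfg, rng)
                if with_clutter:
                    # a box-like object: points at 0.4-0.9 m height
                    pts = np.column_stack(
                        [
                            clutter_rng.uniform(2.9, 3.3, 300),
                            clutter_rng.uniform(2.3, 2.7, 300),
                            clutter_rng.uniform(0.4, 0.9, 300),
                        ]
                    )
                    col, row, z = cam.project(
                        np.column_stack([pts[:, 0], pts[:, 1], pts[:, 2]])
                    )
                    ok = (z > 0.4) & (col >= 0) & (col < 640) & (row >= 0) & (row < 480)
                    d = depth.copy()
                    d[row[ok].astype(int), col[ok].astype(int)] = (z[ok] * 1000).astype(
                        np.uint16
                    )
                    depth = d
                tracks = tracker.step(DepthFrame(depth=depth, t=i / 15))
                confirmed = [t for t in tracks if t.status == "confirmed"]
                if confirmed:
                    est.append(estimate_position(confirmed[0]))
            return np.array(est)

        a, b = run(False), run(True)
        assert len(a) == len(b)
        assert np.sqrt(np.mean((a - b) ** 2)) < 0.02
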