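"""ROI geometry, the 80-point grid, similarity transforms, point tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsefuse.geometry import (
    FaceBox,
    PointGrid,
    RoiRect,
    SimilarityTransform,
    apply_transform,
    compute_rois,
    estimate_similarity,
    lk_window_for_face,
    make_point_grid,
    pyramidal_lucas_kanade,
    track_points,
    track_video,
)


def _roi(rois, name):
    return next(r for r in rois if r.name == name)


class TestComputeRois:
    def test_forehead_fractions(self):
        r = _roi(compute_rois(FaceBox(0, 0, 100, 100)), "forehead")
        assert (r.x0, r.y0, r.x1, r.y1) == (25, 0, 75, 20)

    def test_left_cheek_fractions(self):
        r = _roi(compute_rois(FaceBox(0, 0, 100, 100)), "left_cheek")
        assert (r.x0, r.y0, r.x1, r.y1) == (20, 45, 35, 70)

    def test_right_cheek_mirrors_left(self):
        rois = compute_rois(FaceBox(0, 0, 100, 100))
        left, right = _roi(rois, "left_cheek"), _roi(rois, "right_cheek")
        assert (right.x0, right.x1) == (65, 80)
        assert (right.y0, right.y1) == (left.y0, left.y1)

    def test_offset_face(self):
        r = _roi(compute_rois(FaceBox(10, 20, 200, 100)), "forehead")
        assert (r.x0, r.y0, r.x1, r.y1) == (60, 20, 160, 40)

    def test_nose_band_vertically_centered(self):
        r = _roi(compute_rois(FaceBox(0, 0, 200, 200)), "nose")
        assert (r.y0, r.y1) == (75, 125)  # middle 25% of the height

    def test_degenerate_face_raises(self):
        with pytest.raises(ValueError):
            compute_rois(FaceBox(0, 0, 15, 100))

    @settings(max_examples=50, deadline=None)
    @given(
        dx=st.integers(-500, 500),
        dy=st.integers(-500, 500),
    )
    def test_translation_equivariance(self, dx, dy):
        base = compute_rois(FaceBox(0, 0, 120, 160))
        moved = compute_rois(FaceBox(dx, dy, 120, 160))
        for a, b in zip(base, moved):
            assert (b.x0 - a.x0, b.y0 - a.y0) == (dx, dy)
            assert (b.x1 - a.x1, b.y1 - a.y1) == (dx, dy)


class TestPointGrid:
    def test_counts_and_labels(self):
        rois = compute_rois(FaceBox(0, 0, 160, 160))
        grid = make_point_grid(_roi(rois, "forehead"), _roi(rois, "nose"))
        assert grid.points.shape == (80, 2)
        assert grid.region.count("forehead") == 32
        assert grid.region.count("nose") == 48

    def test_cell_centers(self):
        grid = make_point_grid(
            RoiRect("forehead", 0, 0, 80, 40), RoiRect("nose", 0, 0, 80, 60)
        )
        # forehead 8x4 of 10x10-px cells: first center at (5, 5)
        np.testing.assert_allclose(grid.points[0], [5.0, 5.0])
        np.testing.assert_allclose(grid.points[1], [15.0, 5.0])  # row-major
        nose = grid.points[32:]
        assert len(nose) == 48
        np.testing.assert_allclose(nose[0], [5.0, 5.0])

    def test_points_inside_rects(self):
        rois = compute_rois(FaceBox(30, 40, 200, 240))
        fh, ns = _roi(rois, "forehead"), _roi(rois, "nose")
        grid = make_point_grid(fh, ns)
        for (x, y), region in zip(grid.points, grid.region):
            r = fh if region == "forehead" else ns
            assert r.x0 <= x < r.x1 and r.y0 <= y < r.y1

    def test_too_small_rect_raises(self):
        with pytest.raises(ValueError):
            make_point_grid(
                RoiRect("forehead", 0, 0, 10, 4), RoiRect("nose", 0, 0, 80, 60)
            )

    def test_grid_invariant_enforced(self):
        with pytest.raises(ValueError):
            PointGrid(np.zeros((80, 2)), ("forehead",) * 80)


class TestSimilarity:
    def test_identity(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [2, 3]])
        t = estimate_similarity(pts, pts)
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0, abs=1e-12)
        assert (t.tx, t.ty) == (pytest.approx(0, abs=1e-12),) * 2

    def test_pure_translation(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        t = estimate_similarity(pts, pts + [5.0, 3.0])
        assert t.scale == pytest.approx(1.0, abs=1e-9)
        assert t.tx == pytest.approx(5.0, abs=1e-9)
        assert t.ty == pytest.approx(3.0, abs=1e-9)

    def test_recovers_known_transform(self, rng):
        truth = SimilarityTransform(
            scale=1.1, rotation=np.deg2rad(10), tx=2.0, ty=-4.0
        )
        src = rng.uniform(-10, 10, size=(5, 2))
        t = estimate_similarity(src, truth.apply(src))
        assert t.scale == pytest.approx(truth.scale, abs=1e-6)
        assert t.rotation == pytest.approx(truth.rotation, abs=1e-6)
        assert t.tx == pytest.approx(truth.tx, abs=1e-6)
        assert t.ty == pytest.approx(truth.ty, abs=1e-6)

    def test_noiseless_residual_tiny(self, rng):
        truth = SimilarityTransform(0.9, 0.3, -1.0, 2.5)
        src = rng.uniform(-5, 5, size=(6, 2))
        t = estimate_similarity(src, truth.apply(src))
        resid = np.abs(t.apply(src) - truth.apply(src)).max()
        assert resid < 1e-9

    def test_coincident_points_raise(self):
        pts = np.ones((4, 2))
        with pytest.raises(ValueError):
            estimate_similarity(pts, pts)

    def test_inverse_composes_to_identity(self):
        t = SimilarityTransform(1.3, 0.4, 5.0, -2.0)
        pts = np.array([[1.0, 2], [3, 4], [-2, 7]])
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts,
                                   atol=1e-12)


class TestApplyTransform:
    def test_identity_keeps_rect(self):
        r = RoiRect("nose", 3, 4, 13, 14)
        t = SimilarityTransform(1.0, 0.0, 0.0, 0.0)
        assert apply_transform(t, r) == r

    def test_translation(self):
        r = RoiRect("nose", 0, 0, 10, 10)
        out = apply_transform(SimilarityTransform(1.0, 0.0, 3.0, 0.0), r)
        assert (out.x0, out.y0, out.x1, out.y1) == (3, 0, 13, 10)

    def test_scale_about_origin(self):
        r = RoiRect("nose", 1, 1, 2, 2)
        out = apply_transform(SimilarityTransform(2.0, 0.0, 0.0, 0.0), r)
        assert (out.x0, out.y0, out.x1, out.y1) == (2, 2, 4, 4)


def _textured_frame(rng, shape=(120, 160)):
    from scipy import ndimage

    return ndimage.gaussian_filter(
        rng.uniform(0, 255, size=shape), sigma=1.0
    )


def _grid_for_frame():
    rois = compute_rois(FaceBox(30, 20, 100, 90))
    return make_point_grid(
        next(r for r in rois if r.name == "forehead"),
        next(r for r in rois if r.name == "nose"),
    )


class TestTracking:
    def test_identical_frames_zero_flow(self, rng):
        frame = _textured_frame(rng)
        grid = _grid_for_frame()
        new, redetect = track_points(frame, frame, grid, window=11)
        np.testing.assert_allclose(new.points, grid.points, atol=0.05)
        assert redetect is False

    def test_small_shift_tracked(self, rng):
        from scipy import ndimage

        frame = _textured_frame(rng)
        shifted = ndimage.shift(frame, (0.0, 2.0), order=1, mode="nearest")
        grid = _grid_for_frame()
        new, redetect = track_points(frame, shifted, grid, window=11)
        dx = new.points[:, 0] - grid.points[:, 0]
        assert np.median(dx) == pytest.approx(2.0, abs=0.5)
        assert redetect is False

    def test_large_jump_triggers_redetect(self, rng):
        from scipy import ndimage

        frame = _textured_frame(rng)
        shifted = ndimage.shift(frame, (12.0, 0.0), order=1, mode="nearest")
        grid = _grid_for_frame()
        _, redetect = track_points(frame, shifted, grid, window=11)
        assert redetect is True

    def test_redetect_predicate_monotone(self):
        """Any displacement set exceeding a triggering one also triggers."""
        frame = np.zeros((50, 50))

        def fake_engine(shift):
            def engine(prev, nxt, pts, window):
                return pts + [shift, 0.0], np.ones(len(pts), dtype=bool)

            return engine

        grid = make_point_grid(
            RoiRect("forehead", 2, 2, 42, 22), RoiRect("nose", 2, 24, 42, 48)
        )
        _, small = track_points(frame, frame, grid, 11, engine=fake_engine(9.0))
        _, at_edge = track_points(frame, frame, grid, 11, engine=fake_engine(10.5))
        _, large = track_points(frame, frame, grid, 11, engine=fake_engine(20.0))
        assert small is False and at_edge is True and large is True

    def test_failed_points_carried_over(self):
        flat = np.zeros((60, 60))  # no texture anywhere: every solve fails
        grid = make_point_grid(
            RoiRect("forehead", 5, 5, 45, 25), RoiRect("nose", 5, 27, 45, 51)
        )
        new, redetect = track_points(flat, flat, grid, window=11)
        np.testing.assert_array_equal(new.points, grid.points)
        assert redetect is False

    def test_window_size_rule(self):
        assert lk_window_for_face(FaceBox(0, 0, 140, 120)) == 14
        assert lk_window_for_face(FaceBox(0, 0, 95, 120)) == 12


class TestTrackVideo:
    def test_static_clip_constant_trajectories(self, rng):
        frame = np.dstack([_textured_frame(rng)] * 3)
        frames = [frame] * 40  # short static clip
        # pad frames so >= 64 not needed here: track_video has no minimum
        res = track_video(frames, {0: FaceBox(30, 20, 100, 90)}, fps=30.0)
        assert res.trajectories.n_points == 80
        assert res.trajectories.n_frames == 40
        assert np.abs(np.diff(res.trajectories.ys, axis=1)).max() < 0.1
        assert res.reset_frames == []

    def test_missing_face_box_raises(self, rng):
        frames = [np.zeros((60, 60))] * 3
        with pytest.raises(ValueError):
            track_video(frames, {}, fps=30.0)
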