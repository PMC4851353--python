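"""Detection stage: segmentation, boundary curvature, head placement, chain fit."""

import numpy as np
import pytest

from conftest import render_fish_frame
from fishchain.detection import (
    BoundaryCurve,
    DetectionParams,
    compute_curvature,
    detect_frame,
    estimate_background,
    extract_boundary,
    find_nose_tail,
    fit_chain_detection,
    head_from_nose,
    robust_background,
    segment_foreground,
)
from fishchain.model import build_pose, render_pose, wrap_angle
from fishchain.synthetic import render_silhouette


def analytic_circle(radius: float, spacing: float = 1.0,
                    center=(50.0, 50.0)) -> BoundaryCurve:
    """Equal-arc resampled circle, free of rasterization artifacts."""
    n = int(round(2 * np.pi * radius / spacing))
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    # clockwise in raw coords = counter-clockwise on screen (y down)
    pts = np.stack(
        [center[0] + radius * np.cos(-t), center[1] + radius * np.sin(-t)],
        axis=1,
    )
    return BoundaryCurve(B=pts, spacing=spacing)


class TestBackground:
    def test_single_frame_is_identity(self):
        f = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(estimate_background([f]), f)

    def test_two_constant_frames_average(self):
        a = np.full((4, 4), 10.0)
        b = np.full((4, 4), 20.0)
        assert np.allclose(estimate_background([a, b]), 15.0)

    def test_mismatched_dims_rejected(self):
        with pytest.raises(ValueError):
            estimate_background([np.zeros((3, 3)), np.zeros((4, 4))])

    def test_mean_of_moving_fish_matches_direct_mean(self, spec):
        rng = np.random.default_rng(0)
        frames = []
        for t in range(60):
            pose = build_pose((120 + 5 * t, 100), np.zeros(spec.n_r), spec)
            img, _ = render_fish_frame(pose, spec, (220, 480),
                                       noise_sigma=2.0, rng=rng)
            frames.append(img)
        bg = estimate_background(frames)
        assert np.allclose(bg, np.mean(frames, axis=0))
        # pixels the fish never covered are at the plate level
        assert abs(bg[10, 10] - 200.0) < 3.0

    def test_quantile_background_ignores_transient_fish(self, spec):
        frames = []
        for t in range(40):
            pose = build_pose((120 + 8 * t, 100), np.zeros(spec.n_r), spec)
            img, _ = render_fish_frame(pose, spec, (220, 600))
            frames.append(img)
        bg = robust_background(frames)
        assert bg.min() > 150.0  # no residual fish imprint anywhere


class TestSegmentation:
    def test_identical_frame_gives_empty_mask(self):
        f = np.full((10, 10), 120.0)
        assert not segment_foreground(f, f, 10).any()

    def test_rendered_fish_recovered(self, spec, straight_pose):
        img, sil = render_fish_frame(straight_pose, spec, (260, 420))
        mask = segment_foreground(img, np.full((260, 420), 200.0), 50)
        assert np.array_equal(mask, sil)

    def test_maximal_threshold_gives_empty_mask(self, spec, straight_pose):
        img, _ = render_fish_frame(straight_pose, spec, (260, 420))
        assert not segment_foreground(img, np.full((260, 420), 200.0), 255).any()


class TestBoundary:
    def test_rectangle_perimeter_point_count(self):
        mask = np.zeros((60, 140), dtype=bool)
        mask[20:40, 20:120] = True  # 100 x 20 rectangle, perimeter 240
        curves = extract_boundary(mask, spacing=1.0)
        assert len(curves) == 1
        assert curves[0].n_bw == pytest.approx(240, rel=0.05)

    def test_disk_circumference_point_count(self):
        from skimage.draw import disk

        mask = np.zeros((100, 100), dtype=bool)
        rr, cc = disk((50, 50), 20.5)
        mask[rr, cc] = True
        curves = extract_boundary(mask, spacing=1.0)
        assert curves[0].n_bw == pytest.approx(2 * np.pi * 20.5, rel=0.1)

    def test_two_blobs_two_curves(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:30, 10:30] = True
        mask[60:80, 60:80] = True
        assert len(extract_boundary(mask, spacing=1.0)) == 2

    def test_min_area_drops_specks(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:40, 10:40] = True
        mask[80:83, 80:83] = True
        assert len(extract_boundary(mask, spacing=1.0, min_area=100)) == 1

    def test_equal_arc_spacing(self, spec, straight_pose):
        sil = render_silhouette(straight_pose, spec, (260, 420))
        (curve,) = extract_boundary(sil, spacing=1.0)
        steps = np.linalg.norm(
            np.diff(np.vstack([curve.B, curve.B[:1]]), axis=0), axis=1
        )
        assert steps == pytest.approx(np.full_like(steps, steps.mean()), abs=0.2)


class TestCurvature:
    def test_circle_curvature_matches_inverse_radius(self):
        curve = analytic_circle(20.0)
        prof = compute_curvature(curve, neighbor_arc=8)
        assert np.all(np.abs(prof.C) == pytest.approx(1 / 20.0, rel=0.1))

    def test_total_turning_is_two_pi(self):
        curve = analytic_circle(20.0)
        prof = compute_curvature(curve, neighbor_arc=8)
        assert np.sum(prof.C * curve.spacing) == pytest.approx(2 * np.pi, rel=0.05)

    def test_convex_curve_bends_one_way(self):
        prof = compute_curvature(analytic_circle(30.0), neighbor_arc=8)
        assert np.all(prof.C >= 0)

    def test_straight_run_has_zero_curvature(self, spec, straight_pose):
        sil = render_silhouette(straight_pose, spec, (260, 420))
        (curve,) = extract_boundary(sil, spacing=1.0)
        prof = compute_curvature(curve, neighbor_arc=8, smooth_window=5)
        # the long flat flank of the head rectangle region
        flat = np.sort(np.abs(prof.C))[: curve.n_bw // 4]
        assert np.all(flat < 0.02)

    def test_short_curve_rejected(self):
        curve = BoundaryCurve(B=np.zeros((10, 2)), spacing=1.0)
        with pytest.raises(ValueError):
            compute_curvature(curve, neighbor_arc=8)

    def test_total_turning_on_rasterized_fish(self, spec, straight_pose):
        sil = render_silhouette(straight_pose, spec, (260, 420))
        (curve,) = extract_boundary(sil, spacing=1.0)
        prof = compute_curvature(curve, neighbor_arc=8, smooth_window=5)
        assert np.sum(prof.C * curve.spacing) == pytest.approx(2 * np.pi, rel=0.05)


class TestNoseTail:
    def _fish_profile(self, spec, thetas, shape=(320, 460)):
        pose = build_pose((330, 160), thetas, spec)
        sil = render_silhouette(pose, spec, shape)
        (curve,) = extract_boundary(sil, spacing=1.0)
        prof = compute_curvature(curve, neighbor_arc=8, smooth_window=5)
        return pose, curve, prof

    def test_isolated_fish_gives_nose_and_tail(self, spec):
        pose, curve, prof = self._fish_profile(spec, np.zeros(spec.n_r))
        result = find_nose_tail(prof, kappa_min=0.08)
        assert len(result) == 1
        nose_idx, tail_idx = result[0]
        assert tail_idx is not None
        # the lower peak is the nose, located at the true nose point
        assert prof.C[nose_idx] < prof.C[tail_idx]
        assert np.linalg.norm(curve.B[nose_idx] - pose.N) < 3.0
        assert np.linalg.norm(curve.B[tail_idx] - pose.O) < 8.0

    def test_circle_yields_no_candidates(self):
        prof = compute_curvature(analytic_circle(30.0), neighbor_arc=8)
        assert find_nose_tail(prof, kappa_min=0.08) == []

    @staticmethod
    def _tail_occluded_pair(spec):
        # fish 1 horizontal; fish 2 heading up, its midbody lying across
        # fish 1's tail: one merged blob, both heads free
        p1 = build_pose((330, 200), np.zeros(spec.n_r), spec)
        p2 = build_pose((85, 60), np.full(spec.n_r, np.pi / 2), spec)
        sil = render_silhouette(p1, spec, (400, 460)) | render_silhouette(
            p2, spec, (400, 460)
        )
        curves = extract_boundary(sil, spacing=1.0)
        merged = max(curves, key=lambda c: c.n_bw)
        prof = compute_curvature(merged, neighbor_arc=8, smooth_window=5)
        return p1, p2, merged, prof

    def test_negative_corners_never_candidates(self, spec):
        # the concave intersection corners of an occluding pair must not
        # appear among nose candidates
        _p1, _p2, merged, prof = self._tail_occluded_pair(spec)
        cands = find_nose_tail(prof, kappa_min=0.08)
        assert cands
        assert all(prof.C[i] > 0 for i, _ in cands)

    def test_tail_occlusion_keeps_both_noses(self, spec):
        p1, p2, merged, prof = self._tail_occluded_pair(spec)
        cands = find_nose_tail(prof, kappa_min=0.08)
        assert len(cands) >= 2
        found = [merged.B[i] for i, _ in cands]
        for nose in (p1.N, p2.N):
            assert min(np.linalg.norm(f - nose) for f in found) < 5.0


class TestHeadFromNose:
    def _detect_head(self, spec, thetas, shape=(320, 460), origin=(330, 160)):
        pose = build_pose(origin, thetas, spec)
        img, sil = render_fish_frame(pose, spec, shape)
        (curve,) = extract_boundary(sil, spacing=1.0)
        prof = compute_curvature(curve, neighbor_arc=8, smooth_window=5)
        ((nose_idx, _tail),) = find_nose_tail(prof, kappa_min=0.08)
        return pose, head_from_nose(curve, nose_idx, spec, img, profile=prof)

    def test_recovered_orientation(self, spec):
        pose, head = self._detect_head(spec, np.zeros(spec.n_r))
        assert abs(np.degrees(wrap_angle(head.theta_1 - 0.0))) < 3.0

    def test_j1_placement_geometry(self, spec):
        pose, head = self._detect_head(spec, np.zeros(spec.n_r))
        # J_1 sits len_1 behind the front edge, which is nose_margin ahead
        # of the nose: J_1 = N - (len_1 - margin) * heading
        assert np.linalg.norm(head.J_1 - pose.J[0]) < 3.0

    def test_patch_dimensions_match_head_rectangle(self, spec):
        _pose, head = self._detect_head(spec, np.zeros(spec.n_r))
        assert head.patch.shape == (spec.widths[0], spec.lengths[0])

    def test_mirror_flip_mirrors_orientation(self, spec):
        pose = build_pose((330, 160), np.full(spec.n_r, 0.4), spec)
        img, sil = render_fish_frame(pose, spec, (320, 460))
        for frame in (img, img[::-1]):
            mask = segment_foreground(frame, np.full(frame.shape, 200.0), 50)
            (curve,) = extract_boundary(mask, spacing=1.0)
            prof = compute_curvature(curve, neighbor_arc=8, smooth_window=5)
            ((nose_idx, _),) = find_nose_tail(prof, kappa_min=0.08)
            head = head_from_nose(curve, nose_idx, spec, frame, profile=prof)
            if frame is img:
                theta_orig = head.theta_1
            else:
                theta_flip = head.theta_1
        # flipping y negates the heading in the (x, -y) convention
        assert abs(np.degrees(wrap_angle(theta_flip + theta_orig))) < 3.0


class TestChainFit:
    def test_straight_fish_recovered(self, spec, straight_pose):
        # render-and-recover with the exact rectangle union as the region
        region = render_pose(straight_pose, spec, (260, 420))
        fit = fit_chain_detection(
            straight_pose.J[0], 0.0, spec, region, n_pb=256, rng=7
        )
        assert fit.cover_ratio >= 0.9
        err = np.degrees(np.abs([float(wrap_angle(t)) for t in fit.theta[1:]]))
        assert np.all(err < 10.0)

    def test_s_curved_fish_recovered(self, spec):
        bends = np.radians([0, 30, -30, 30, -30, 30, -30, 30])
        pose = build_pose((340, 200), bends, spec)
        region = render_pose(pose, spec, (400, 460))
        fit = fit_chain_detection(pose.J[0], bends[0], spec, region, n_pb=256, rng=11)
        assert fit.cover_ratio >= 0.8
        assert np.all(np.linalg.norm(fit.J - pose.J, axis=1) <= 5.0)

    def test_empty_region_is_invalid(self, spec):
        fit = fit_chain_detection(
            (50.0, 50.0), 0.0, spec, np.zeros((100, 100), dtype=bool), n_pb=32,
            rng=0,
        )
        assert fit.cover_ratio == 0.0

    def test_seeded_fit_is_deterministic(self, spec, straight_pose):
        sil = render_silhouette(straight_pose, spec, (260, 420))
        a = fit_chain_detection(straight_pose.J[0], 0.0, spec, sil, 128, rng=3)
        b = fit_chain_detection(straight_pose.J[0], 0.0, spec, sil, 128, rng=3)
        assert np.array_equal(a.theta, b.theta)


class TestDetectFrame:
    def test_blank_frame_yields_nothing(self, spec):
        frame = np.full((300, 300), 200.0)
        dets = detect_frame(frame, frame, DetectionParams(), spec, rng=0)
        assert dets == []

    def test_well_separated_fish_all_found(self, spec):
        rng = np.random.default_rng(5)
        canvas = np.full((800, 1700), 200.0)
        poses = []
        for i in range(4):
            pose = build_pose((330 + 400 * i, 200 + 180 * (i % 2)),
                              np.full(spec.n_r, rng.uniform(0, 2 * np.pi)), spec)
            sil = render_silhouette(pose, spec, canvas.shape)
            canvas[sil] = 40.0
            poses.append(pose)
        params = DetectionParams(fish_area=4600)
        dets = detect_frame(canvas, np.full(canvas.shape, 200.0), params, spec, rng=1)
        assert len(dets) == 4
        for pose in poses:
            best = min(np.linalg.norm(d.pose.N - pose.N) for d in dets)
            assert best < 3.0

    def test_rotation_equivariance_quarter_turn(self, spec):
        pose = build_pose((330, 160), np.zeros(spec.n_r), spec)
        img, _ = render_fish_frame(pose, spec, (460, 460))
        params = DetectionParams(fish_area=4600)
        (d0,) = detect_frame(img, np.full(img.shape, 200.0), params, spec, rng=2)
        rot = np.rot90(img, k=-1).copy()
        (d1,) = detect_frame(rot, np.full(rot.shape, 200.0), params, spec, rng=2)
        H = img.shape[0]
        expected_N = np.array([H - 1 - d0.pose.N[1], d0.pose.N[0]])
        assert np.linalg.norm(d1.pose.N - expected_N) < 2.0
        assert abs(np.degrees(wrap_angle(d1.pose.theta[0] - (d0.pose.theta[0] - np.pi / 2)))) < 3.0
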