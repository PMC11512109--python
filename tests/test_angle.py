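import math

import numpy as np
import pytest

from rootangle.angle import (
    SegmentSelectionError,
    angle_between,
    annulus_filter,
    measure_masks,
    select_extreme_segments,
    skeletonize_mask,
    total_root_length,
)
from rootangle.config import RunConfig
from rootangle.scenes import SceneTruth, generate_multi_scene, generate_scene
from rootangle.seeds import SeedPoint


def seed_at(x, y):
    return SeedPoint(x=float(x), y=int(y), area=100)


class TestSkeletonize:
    def test_empty_mask(self):
        m = np.zeros((5, 5), bool)
        assert skeletonize_mask(m).sum() == 0

    def test_thick_bar_thins_to_subset_line(self):
        m = np.zeros((120, 20), bool)
        m[10:110, 5:10] = True
        s = skeletonize_mask(m)
        assert (s & ~m).sum() == 0  # subset of input
        # no 2x2 all-foreground block: 1-px wide
        blocks = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        assert not blocks.any()
        assert s.sum() >= 90

    def test_single_isolated_pixel_retained(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        assert skeletonize_mask(m)[3, 3]


class TestAnnulusFilter:
    def test_closed_bounds(self):
        m = np.zeros((60, 60), bool)
        m[30, 40] = True  # distance exactly 10 from (30, 30)
        out = annulus_filter(m, seed_at(30, 30), inner_radius=10, outer_radius=20)
        assert out[30, 40]
        m2 = np.zeros((60, 60), bool)
        m2[30, 51] = True  # distance 21 = outer + 1
        out2 = annulus_filter(m2, seed_at(30, 30), 10, 20)
        assert not out2.any()

    def test_inside_inner_removed(self):
        m = np.zeros((60, 60), bool)
        m[30, 35] = True
        assert not annulus_filter(m, seed_at(30, 30), 10, 20).any()

    def test_seed_at_corner_clips_without_error(self):
        m = np.ones((30, 30), bool)
        out = annulus_filter(m, seed_at(0, 0), 5, 12)
        ys, xs = np.nonzero(out)
        d = np.hypot(xs, ys)
        assert ((d >= 5) & (d <= 12)).all() and out.any()


class TestSelectExtremeSegments:
    def _mask_with_columns(self, cols):
        m = np.zeros((30, 200), bool)
        for c in cols:
            m[5:15, c] = True
        return m

    def test_left_and_right_by_centroid(self):
        m = self._mask_with_columns([40, 160])
        left, right = select_extreme_segments(m)
        assert left.centroid[0] == 40.0 and right.centroid[0] == 160.0

    def test_middle_component_ignored(self):
        m = self._mask_with_columns([40, 100, 160])
        left, right = select_extreme_segments(m)
        assert left.centroid[0] == 40.0 and right.centroid[0] == 160.0

    def test_zero_and_one_component_errors(self):
        with pytest.raises(SegmentSelectionError, match="no_root_segments"):
            select_extreme_segments(np.zeros((5, 5), bool))
        with pytest.raises(SegmentSelectionError, match="one_root_segment"):
            select_extreme_segments(self._mask_with_columns([40]))


class TestAngleBetween:
    @pytest.mark.parametrize(
        "seed,left,right,expected",
        [
            ((100, 50), (60, 90), (140, 90), 90.0),
            ((100, 50), (60, 90), (100, 90), 45.0),
            ((100, 50), (100, 150), (100, 150), 0.0),
        ],
    )
    def test_hand_examples(self, seed, left, right, expected):
        assert angle_between(seed, left, right) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_centroid_on_seed(self):
        with pytest.raises(SegmentSelectionError):
            angle_between((10.0, 10.0), (10.0, 10.0), (20.0, 20.0))

    def test_matches_law_of_cosines_oracle(self, rng):
        for _ in range(1000):
            s, l, r = rng.uniform(-100, 100, size=(3, 2))
            if np.allclose(s, l) or np.allclose(s, r):
                continue
            a = np.linalg.norm(l - s)
            b = np.linalg.norm(r - s)
            c = np.linalg.norm(l - r)
            cosv = np.clip((a * a + b * b - c * c) / (2 * a * b), -1.0, 1.0)
            oracle = math.degrees(math.acos(cosv))
            assert angle_between(tuple(s), tuple(l), tuple(r)) == pytest.approx(
                oracle, abs=1e-9
            )


class TestTotalRootLength:
    def test_empty_mask(self):
        assert total_root_length(np.zeros((5, 5), bool)) == 0.0

    def test_horizontal_line(self):
        m = np.zeros((5, 20), bool)
        m[2, 3:14] = True  # 11 px
        assert total_root_length(m) == pytest.approx(10.0, abs=0)

    def test_diagonal_line(self):
        m = np.zeros((20, 20), bool)
        for i in range(11):
            m[3 + i, 3 + i] = True
        assert total_root_length(m) == pytest.approx(10 * math.sqrt(2), abs=1e-12)

    def test_bresenham_polyline_matches_step_oracle(self):
        # corners turn by 135 degrees so thinning cannot shortcut them
        from skimage.draw import line

        m = np.zeros((80, 80), bool)
        pts = [(5, 40), (40, 40), (70, 70)]
        ideal = 0.0
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            rr, cc = line(y0, x0, y1, x1)
            # step-length oracle: sum of unit/diagonal moves along the chain
            for k in range(1, len(rr)):
                ideal += math.sqrt(
                    (rr[k] - rr[k - 1]) ** 2 + (cc[k] - cc[k - 1]) ** 2
                )
            m[rr, cc] = True
        assert total_root_length(m) == pytest.approx(ideal, abs=1e-9)

    def test_thick_bar_within_3_percent(self):
        m = np.zeros((320, 40), bool)
        m[10:310, 10:15] = True  # 5 px wide, 300 long
        assert total_root_length(m) == pytest.approx(300.0, rel=0.03)

    def test_min_component_area_filters_specks(self):
        m = np.zeros((50, 50), bool)
        m[10:40, 20:25] = True
        with_speck = m.copy()
        with_speck[2:4, 2:4] = True
        assert total_root_length(with_speck, min_component_area=100) == (
            total_root_length(m)
        )


class TestMeasureMasks:
    def test_clean_scene_recovers_angle(self, clean_scene, default_config):
        root, seed, truth = clean_scene
        recs = measure_masks(root, seed, default_config)
        assert len(recs) == 1 and recs[0].error == ""
        assert recs[0].angle_degrees == pytest.approx(truth.analytic_angle, abs=2.0)

    def test_empty_root_mask_reports_no_root_segments(self, clean_scene, default_config):
        _, seed, _ = clean_scene
        recs = measure_masks(np.zeros_like(seed), seed, default_config)
        assert len(recs) == 1 and recs[0].error == "no_root_segments"
        assert recs[0].angle_degrees is None

    def test_empty_seed_mask_reports_no_seed(self, clean_scene, default_config):
        root, seed, _ = clean_scene
        recs = measure_masks(root, np.zeros_like(seed), default_config)
        assert len(recs) == 1 and recs[0].error == "no_seed"

    def test_two_plants_ordered_left_to_right(self, default_config):
        truths = [
            SceneTruth(seed_xy=(300, 150), true_angle=70.0),
            SceneTruth(seed_xy=(1000, 150), true_angle=110.0),
        ]
        root, seed, _ = generate_multi_scene(truths, image_size=(1400, 1200))
        recs = measure_masks(root, seed, default_config)
        assert [r.seed_index for r in recs] == [0, 1]
        assert recs[0].angle_degrees == pytest.approx(70.0, abs=2.0)
        assert recs[1].angle_degrees == pytest.approx(110.0, abs=2.0)

    def test_occlusion_inside_inner_radius_never_changes_angle(self, default_config):
        base = SceneTruth(true_angle=80.0)
        occluded = SceneTruth(
            true_angle=80.0, occlusions=(("left", 10.0, 40.0), ("right", 5.0, 30.0))
        )
        r0, s0, _ = generate_scene(base)
        r1, s1, _ = generate_scene(occluded)
        a0 = measure_masks(r0, s0, default_config)[0].angle_degrees
        a1 = measure_masks(r1, s1, default_config)[0].angle_degrees
        assert a1 == pytest.approx(a0, abs=1e-9)

    @pytest.mark.parametrize("phi", [-10.0, -5.0, 5.0, 10.0])
    def test_rigid_rotation_within_2_degrees(self, phi, default_config):
        base = SceneTruth(true_angle=90.0)
        rotated = SceneTruth(
            true_angle=90.0, half_angles=(45.0 + phi, 45.0 - phi)
        )
        r0, s0, _ = generate_scene(base)
        r1, s1, _ = generate_scene(rotated)
        a0 = measure_masks(r0, s0, default_config)[0].angle_degrees
        a1 = measure_masks(r1, s1, default_config)[0].angle_degrees
        assert abs(a1 - a0) <= 2.0

    def test_horizontal_mirror_leaves_angle_unchanged(self, default_config):
        truth = SceneTruth(true_angle=77.0, half_angles=(50.0, 27.0))
        root, seed, _ = generate_scene(truth)
        a0 = measure_masks(root, seed, default_config)[0].angle_degrees
        a1 = measure_masks(root[:, ::-1], seed[:, ::-1], default_config)[0].angle_degrees
        assert a1 == pytest.approx(a0, abs=1e-9)

    def test_total_length_repeated_on_every_row(self, default_config):
        truths = [
            SceneTruth(seed_xy=(300, 150), true_angle=70.0),
            SceneTruth(seed_xy=(1000, 150), true_angle=110.0),
        ]
        root, seed, _ = generate_multi_scene(truths, image_size=(1400, 1200))
        recs = measure_masks(root, seed, default_config)
        assert recs[0].total_root_length_px == recs[1].total_root_length_px > 0
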