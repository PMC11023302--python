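"""Motion core: differencing, thresholding, morphology, counting, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestmotion import (
    MotionProfile,
    SurveillanceZone,
    difference_image,
    episode_maximum,
    frame_to_time,
    motion_profiles,
    normalize_profile,
    px_cm_calibration,
    segment_motion,
    zone_counts,
    zone_real_size,
)


class TestDifferenceImage:
    def test_identical_frames_give_zero(self, rng):
        frame = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        assert not difference_image(frame, frame).any()

    def test_single_pixel_change(self):
        a = np.full((8, 8), 100, dtype=np.uint8)
        b = a.copy()
        b[3, 4] = 120
        diff = difference_image(a, b)
        assert diff[3, 4] == 20
        assert diff.sum() == 20

    @pytest.mark.parametrize("channels", [None, 3])
    def test_matches_elementwise_oracle(self, rng, channels):
        shape = (16, 16) if channels is None else (16, 16, channels)
        a = rng.integers(0, 256, shape, dtype=np.uint8)
        b = rng.integers(0, 256, shape, dtype=np.uint8)
        diff = difference_image(a, b)
        for i in range(16):
            for j in range(16):
                if channels is None:
                    expected = abs(int(a[i, j]) - int(b[i, j]))
                else:
                    expected = abs(
                        sum(int(v) for v in a[i, j]) - sum(int(v) for v in b[i, j])
                    )
                assert diff[i, j] == expected

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)"):
            difference_image(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSegmentMotion:
    def test_threshold_is_strict(self):
        diff = np.full((10, 10), 10)
        assert not segment_motion(diff, lum_th=10, morphology=False).any()

    def test_isolated_pixel_removed_by_opening(self):
        diff = np.zeros((15, 15))
        diff[7, 7] = 200
        assert segment_motion(diff, morphology=True).sum() == 0
        assert segment_motion(diff, morphology=False).sum() == 1

    def test_filled_block_preserved_by_opening(self):
        diff = np.zeros((20, 20))
        diff[5:15, 5:15] = 200
        assert segment_motion(diff, morphology=True).sum() == 100

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 300), st.integers(0, 2**32 - 1))
    def test_raising_threshold_never_increases_count(self, th1, th2, seed):
        lo, hi = sorted((th1, th2))
        diff = np.random.default_rng(seed).integers(0, 400, (20, 20))
        assert (
            segment_motion(diff, hi, morphology=False).sum()
            <= segment_motion(diff, lo, morphology=False).sum()
        )

    def test_opening_never_increases_count(self, rng):
        for _ in range(20):
            diff = rng.integers(0, 30, (24, 24))
            assert (
                segment_motion(diff, morphology=True).sum()
                <= segment_motion(diff, morphology=False).sum()
            )


class TestZoneCounts:
    zone = SurveillanceZone("sz", (0, 0, 100, 100))

    def test_all_active_mask_counts_full_area(self):
        [p] = zone_counts([np.ones((120, 120), bool)], [self.zone])
        assert p.counts[0] == 10_000

    def test_all_inactive_mask_counts_zero(self):
        [p] = zone_counts([np.zeros((120, 120), bool)], [self.zone])
        assert p.counts[0] == 0

    def test_checkerboard_counts_half(self):
        mask = np.indices((120, 120)).sum(axis=0) % 2 == 0
        [p] = zone_counts([mask], [self.zone])
        assert p.counts[0] == 5_000

    def test_matches_double_loop_oracle(self, rng):
        zones = [
            SurveillanceZone("a", (3, 5, 20, 17)),
            SurveillanceZone("b", (40, 30, 24, 24)),
        ]
        masks = rng.random((25, 64, 64)) < 0.3
        profiles = zone_counts(list(masks), zones)
        for z, p in zip(zones, profiles):
            r0, c0, h, w = z.rect
            for k, mask in enumerate(masks):
                expected = sum(
                    1 for i in range(r0, r0 + h) for j in range(c0, c0 + w) if mask[i, j]
                )
                assert p.counts[k] == expected

    def test_zone_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            zone_counts([np.zeros((50, 50), bool)], [self.zone])

    def test_shift_invariance(self, rng):
        mask = rng.random((40, 40)) < 0.4
        zone = SurveillanceZone("z", (5, 5, 10, 10))
        shifted_zone = SurveillanceZone("z", (12, 9, 10, 10))
        shifted_mask = np.zeros((60, 60), bool)
        shifted_mask[7:47, 4:44] = mask
        [p0] = zone_counts([mask], [zone])
        [p1] = zone_counts([shifted_mask], [shifted_zone])
        assert p0.counts[0] == p1.counts[0]


class TestNormalization:
    zone = SurveillanceZone("z", (0, 0, 20, 20))

    def _profile(self, counts):
        return MotionProfile(
            zone=self.zone,
            counts=np.asarray(counts),
            frame_indices=np.arange(1, len(counts) + 1),
        )

    def test_linear_scaling(self):
        p = normalize_profile(self._profile([0, 50, 100]), episode_max=100)
        assert np.allclose(p.normalized, [0.0, 0.5, 1.0])

    def test_episode_maximum_is_global_max_over_zones(self, rng):
        profiles = [self._profile(rng.integers(0, 400, 50)) for _ in range(5)]
        brute = max(c for p in profiles for c in p.counts)
        assert episode_maximum(profiles) == brute

    def test_all_zero_episode_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_profile(self._profile([0, 0, 0]), episode_max=0)


class TestCalibration:
    def test_frame_time_anchors(self):
        assert frame_to_time(12_507, 50, "min") == pytest.approx(4.169, abs=5e-4)
        assert frame_to_time(1_216, 50, "s") == pytest.approx(24.32)
        assert frame_to_time(16, 50, "ms") == pytest.approx(320.0)
        assert frame_to_time(0, 50) == 0.0

    def test_px_per_cm_from_nest_width(self):
        assert px_cm_calibration(580, 66) == 8.8
        assert px_cm_calibration(100, 100) == 1.0

    def test_zone_real_world_size(self):
        assert zone_real_size(100, 8.8) == (11.36, 129.05)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            px_cm_calibration(580, 0)


def test_motion_profiles_full_chain(rng):
    """frames -> difference -> threshold -> zone counts on a tiny stack."""
    frames = np.full((5, 30, 30), 100, dtype=np.uint8)
    frames[2, 10:14, 10:14] = 150  # a 4x4 patch flips on at frame 2 and off at 3
    zone = SurveillanceZone("z", (8, 8, 10, 10))
    [p] = motion_profiles(frames, [zone], lum_th=10, morphology=True)
    assert list(p.frame_indices) == [1, 2, 3, 4]
    assert list(p.counts) == [0, 16, 16, 0]
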