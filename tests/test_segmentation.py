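"""Thresholding and per-slice segmentation against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from punctacoloc import (
    Calibration,
    ChannelStack,
    ThresholdSpec,
    count_punctae,
    link_punctae_3d,
    segment_punctae,
    threshold_channel,
)

from conftest import make_stack
from oracles import between_class_variance, flood_fill_components, otsu_bruteforce_max


class TestThreshold:
    def test_bimodal_otsu_separates_classes(self):
        data = np.zeros((1, 4, 4), np.uint16)
        data[0, :2, :] = 100  # 8 background pixels, 8 at 100
        mask, level = threshold_channel(make_stack(data), ThresholdSpec())
        assert 0 <= level < 100
        assert mask.sum() == 8
        assert mask[0, :2, :].all()

    def test_fixed_threshold_is_strict_inequality(self, rng):
        data = rng.integers(0, 256, size=(2, 16, 16)).astype(np.uint16)
        mask, level = threshold_channel(
            make_stack(data), ThresholdSpec(method="fixed", fixed_value=50)
        )
        assert level == 50
        np.testing.assert_array_equal(mask, data > 50)

    @pytest.mark.parametrize("seed", range(20))
    def test_otsu_matches_exhaustive_variance_scan(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 256, size=(1, 16, 16)).astype(np.uint16)
        _, level = threshold_channel(make_stack(data, bit_depth=8), ThresholdSpec())
        achieved = between_class_variance(data, level)
        best = otsu_bruteforce_max(data)
        assert achieved == pytest.approx(best, rel=1e-12)

    def test_constant_input_warns_and_returns_empty_mask(self):
        data = np.full((2, 8, 8), 7, np.uint16)
        with pytest.warns(UserWarning):
            mask, _ = threshold_channel(make_stack(data), ThresholdSpec())
        assert not mask.any()

    def test_per_slice_otsu_returns_one_level_per_slice(self, rng):
        data = rng.integers(0, 1000, size=(3, 32, 32)).astype(np.uint16)
        mask, levels = threshold_channel(
            make_stack(data), ThresholdSpec(per="slice")
        )
        assert len(levels) == 3
        for z, lv in enumerate(levels):
            np.testing.assert_array_equal(mask[z], data[z] > lv)

    def test_threshold_monotonicity(self, rng):
        data = rng.integers(0, 1000, size=(2, 32, 32)).astype(np.uint16)
        stack = make_stack(data)
        m1, _ = threshold_channel(stack, ThresholdSpec(method="fixed", fixed_value=100))
        m2, _ = threshold_channel(stack, ThresholdSpec(method="fixed", fixed_value=400))
        assert not (m2 & ~m1).any()  # higher threshold gives a subset


class TestSegmentation:
    def test_solid_100px_square_retained_with_area_32_5(self):
        mask = np.zeros((1, 20, 20), bool)
        mask[0, 5:15, 5:15] = True  # 10x10 = 100 px
        data = np.where(mask, 500, 0)
        pset = segment_punctae(mask, make_stack(data))
        assert count_punctae(pset) == 1
        p = pset.punctae[0]
        assert p.area_px == 100
        assert p.area_um2 == pytest.approx(32.5)

    def test_99px_component_discarded(self):
        mask = np.zeros((1, 20, 20), bool)
        mask[0, 5:14, 5:16] = True  # 9x11 = 99 px
        data = np.where(mask, 500, 0)
        pset = segment_punctae(mask, make_stack(data))
        assert count_punctae(pset) == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_masks_match_flood_fill_oracle(self, connectivity, rng):
        for _ in range(20):
            mask2d = rng.random((32, 32)) < 0.4
            pset = segment_punctae(
                mask2d[np.newaxis], make_stack(np.ones((32, 32))), min_area_px=1,
                connectivity=connectivity,
            )
            got = {p.pixel_set for p in pset.punctae}
            expected = set(flood_fill_components(mask2d, connectivity))
            assert got == expected

    def test_intensity_summaries_from_unthresholded_stack(self, rng):
        data = rng.integers(0, 4000, size=(1, 20, 20)).astype(np.uint16)
        mask = np.zeros((1, 20, 20), bool)
        mask[0, 2:12, 3:13] = True
        pset = segment_punctae(mask, make_stack(data))
        p = pset.punctae[0]
        vals = data[0, 2:12, 3:13].astype(float)
        assert p.sum_intensity == pytest.approx(vals.sum())
        assert p.mean_intensity == pytest.approx(vals.mean())
        assert p.mean_intensity * p.area_px == pytest.approx(p.sum_intensity, rel=1e-9)

    def test_size_filter_monotonicity(self, rng):
        mask = (rng.random((2, 64, 64)) < 0.55)
        stack = make_stack(np.ones((2, 64, 64)))
        counts = [
            count_punctae(segment_punctae(mask, stack, min_area_px=m))
            for m in (1, 5, 20, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_ordering_deterministic_by_z_then_topleft(self):
        mask = np.zeros((2, 10, 10), bool)
        mask[1, 0:2, 0:2] = True     # z=1, top-left
        mask[0, 6:8, 6:8] = True     # z=0, bottom-right
        mask[0, 0:2, 4:6] = True     # z=0, top
        pset = segment_punctae(mask, make_stack(np.ones((2, 10, 10))), min_area_px=1)
        zs = [p.z_index for p in pset.punctae]
        firsts = [tuple(p.pixels[0]) for p in pset.punctae]
        assert zs == [0, 0, 1]
        assert firsts == [(0, 4), (6, 6), (0, 0)]

    def test_shift_invariance_with_shifted_fixed_threshold(self, rng):
        data = rng.integers(0, 500, size=(1, 32, 32)).astype(np.uint16)
        stack = make_stack(data)
        m1, _ = threshold_channel(stack, ThresholdSpec(method="fixed", fixed_value=200))
        shifted = make_stack(data + 100)
        m2, _ = threshold_channel(shifted, ThresholdSpec(method="fixed", fixed_value=300))
        p1 = segment_punctae(m1, stack, min_area_px=5)
        p2 = segment_punctae(m2, shifted, min_area_px=5)
        assert [p.pixel_set for p in p1.punctae] == [p.pixel_set for p in p2.punctae]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1))
    def test_4x4_masks_match_flood_fill_oracle(self, bits):
        mask2d = np.array(
            [(bits >> k) & 1 for k in range(16)], dtype=bool
        ).reshape(4, 4)
        pset = segment_punctae(
            mask2d[np.newaxis], make_stack(np.ones((4, 4))), min_area_px=1
        )
        assert {p.pixel_set for p in pset.punctae} == set(
            flood_fill_components(mask2d, 8)
        )


class TestLinked3D:
    def test_stacked_squares_link_into_one_object(self):
        mask = np.zeros((3, 10, 10), bool)
        mask[:, 2:6, 2:6] = True
        pset = segment_punctae(mask, make_stack(np.ones((3, 10, 10))), min_area_px=1)
        assert count_punctae(pset) == 3          # 2D default: one per slice
        assert len(link_punctae_3d(pset)) == 1   # 3D-linked: one object

    def test_nonoverlapping_punctae_stay_separate(self):
        mask = np.zeros((2, 10, 10), bool)
        mask[0, 0:3, 0:3] = True
        mask[1, 6:9, 6:9] = True
        pset = segment_punctae(mask, make_stack(np.ones((2, 10, 10))), min_area_px=1)
        assert len(link_punctae_3d(pset)) == 2
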