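"""Radiation-target delineation pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsfit.rt import (
    abnormality_mask,
    apply_exclusions,
    mask_volume_ml,
    nawm_mean,
    primary_component,
    run_rt_pipeline,
)


def flood_fill_components(mask, connectivity):
    """Brute-force component labeling used as an independent oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if any(c < 0 or c >= s for c, s in zip(w, mask.shape)):
                    continue
                if mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        components.append(comp)
    return components


class TestNawmMean:
    def test_uniform_region(self):
        ratio = np.full((4, 4, 4), 1.3)
        mask = np.zeros_like(ratio, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        assert nawm_mean(ratio, mask) == pytest.approx(1.3)

    def test_three_values(self):
        ratio = np.zeros((3, 1, 1))
        ratio[:, 0, 0] = [1.0, 2.0, 3.0]
        mask = np.ones_like(ratio, dtype=bool)
        assert nawm_mean(ratio, mask) == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            nawm_mean(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestAbnormalityMask:
    def test_threshold_boundary_is_inclusive(self):
        ratio = np.full((3, 3, 1), 2.0)
        mask = abnormality_mask(ratio, nawm_reference=1.0, multiplier=2.0)
        assert mask.all()

    def test_below_threshold_excluded(self):
        ratio = np.full((3, 3, 1), 1.99)
        mask = abnormality_mask(ratio, 1.0, 2.0)
        assert not mask.any()

    def test_toy_slice_selects_exactly_supra_voxels(self):
        ratio = np.zeros((3, 3, 1))
        ratio[0, 1, 0] = 2.5
        ratio[2, 2, 0] = 4.0
        ratio[1, 1, 0] = 1.9
        mask = abnormality_mask(ratio, 1.0, 2.0)
        assert mask.sum() == 2
        assert mask[0, 1, 0] and mask[2, 2, 0]

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            abnormality_mask(np.ones((2, 2, 2)), 1.0, 0.0)


class TestApplyExclusions:
    def _empty(self, shape):
        return np.zeros(shape, dtype=bool)

    def test_no_exclusions_is_identity(self):
        shape = (4, 4, 2)
        mask = np.random.default_rng(0).random(shape) > 0.5
        out = apply_exclusions(mask, np.ones(shape, dtype=bool),
                               self._empty(shape), self._empty(shape),
                               self._empty(shape))
        assert np.array_equal(out, mask)

    def test_quality_all_fail_empties_mask(self):
        shape = (4, 4, 2)
        mask = np.ones(shape, dtype=bool)
        out = apply_exclusions(mask, self._empty(shape), self._empty(shape),
                               self._empty(shape), self._empty(shape))
        assert not out.any()

    def test_single_csf_voxel_removed(self):
        shape = (5, 1, 1)
        mask = np.ones(shape, dtype=bool)
        csf = self._empty(shape)
        csf[2, 0, 0] = True
        out = apply_exclusions(mask, np.ones(shape, dtype=bool), csf,
                               self._empty(shape), self._empty(shape))
        assert out.sum() == 4 and not out[2, 0, 0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(np.ones((2, 2, 2), dtype=bool),
                             np.ones((3, 2, 2), dtype=bool),
                             np.zeros((2, 2, 2), dtype=bool),
                             np.zeros((2, 2, 2), dtype=bool),
                             np.zeros((2, 2, 2), dtype=bool))


class TestPrimaryComponent:
    def test_single_blob_returned_unchanged(self):
        mask = np.zeros((6, 6, 3), dtype=bool)
        mask[2:4, 2:4, 1] = True
        assert np.array_equal(primary_component(mask), mask)

    def test_larger_of_two_blobs_selected(self):
        mask = np.zeros((10, 4, 4), dtype=bool)
        mask[0:5, 0, 0] = True  # 5 voxels
        mask[7:10, 2, 2] = True  # 3 voxels
        out = primary_component(mask, connectivity=26)
        comps = flood_fill_components(mask, 26)
        biggest = max(comps, key=len)
        expected = np.zeros_like(mask)
        for v in biggest:
            expected[v] = True
        assert np.array_equal(out, expected)
        assert out.sum() == 5

    def test_diagonal_voxels_connectivity_dependence(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        assert len(flood_fill_components(mask, 26)) == 1
        assert len(flood_fill_components(mask, 6)) == 2
        assert primary_component(mask, connectivity=26).sum() == 2
        assert primary_component(mask, connectivity=6).sum() == 1

    def test_empty_in_empty_out(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        assert not primary_component(mask).any()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        mask = rng.random((8, 8, 4)) > 0.7
        once = primary_component(mask)
        twice = primary_component(once)
        assert np.array_equal(once, twice)

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            primary_component(np.zeros((2, 2, 2), dtype=bool), connectivity=4)


class TestMaskVolume:
    def test_empty_mask_is_zero(self):
        assert mask_volume_ml(np.zeros((3, 3, 3), dtype=bool), 108.0) == 0.0

    def test_thousand_voxels_at_108ul(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert mask_volume_ml(mask, 108.0) == pytest.approx(108.0)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(1)
        a = rng.random((5, 5, 5)) > 0.5
        b = ~a & (rng.random((5, 5, 5)) > 0.5)
        v = mask_volume_ml(a | b, 107.7)
        assert v == pytest.approx(mask_volume_ml(a, 107.7)
                                  + mask_volume_ml(b, 107.7))

    def test_invalid_voxel_volume_rejected(self):
        with pytest.raises(ValueError):
            mask_volume_ml(np.ones((2, 2, 2), dtype=bool), 0.0)


class TestRunPipeline:
    def _masks(self, shape, nawm):
        empty = np.zeros(shape, dtype=bool)
        return {
            "nawm": nawm,
            "quality": np.ones(shape, dtype=bool),
            "csf": empty.copy(),
            "cerebellum": empty.copy(),
            "brainstem": empty.copy(),
        }

    def test_flat_map_yields_empty_target(self):
        shape = (6, 6, 4)
        ratio = np.full(shape, 0.5)
        nawm = np.zeros(shape, dtype=bool)
        nawm[4:, 4:, :2] = True
        result = run_rt_pipeline(ratio, self._masks(shape, nawm))
        assert not result.target_mask.any()
        assert result.volume_ml == 0.0
        assert result.threshold_value == pytest.approx(1.0)

    def test_hot_blob_detected_and_measured(self):
        shape = (8, 8, 4)
        ratio = np.full(shape, 0.5)
        ratio[2:4, 2:4, 1:3] = 2.0  # 8 voxels, 4x the NAWM level
        nawm = np.zeros(shape, dtype=bool)
        nawm[6:, 6:, :] = True
        result = run_rt_pipeline(ratio, self._masks(shape, nawm),
                                 voxel_volume_ul=108.0)
        assert result.target_mask.sum() == 8
        assert result.volume_ml == pytest.approx(8 * 108.0 / 1000)
        assert result.n_components_before_selection == 1

    def test_exclusions_remove_component(self):
        shape = (8, 8, 4)
        ratio = np.full(shape, 0.5)
        ratio[1:3, 1:3, 1] = 2.0
        ratio[5:8, 5:8, 2] = 2.0  # larger blob but in CSF
        nawm = np.zeros(shape, dtype=bool)
        nawm[0, 6:, :] = True
        masks = self._masks(shape, nawm)
        masks["csf"][5:8, 5:8, 2] = True
        result = run_rt_pipeline(ratio, masks)
        assert result.target_mask.sum() == 4
        assert result.target_mask[1:3, 1:3, 1].all()

    @given(multipliers=st.lists(
        st.floats(0.5, 5.0), min_size=2, max_size=4, unique=True))
    @settings(max_examples=15, deadline=None)
    def test_target_shrinks_as_multiplier_grows(self, multipliers):
        rng = np.random.default_rng(11)
        shape = (8, 8, 4)
        ratio = rng.uniform(0, 3.0, shape)
        nawm = np.zeros(shape, dtype=bool)
        nawm[:2, :2, :] = True
        masks = self._masks(shape, nawm)
        sizes = [
            run_rt_pipeline(ratio, masks, multiplier=m).target_mask.sum()
            for m in sorted(multipliers)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_mask_rejected(self):
        shape = (4, 4, 2)
        masks = self._masks(shape, np.ones(shape, dtype=bool))
        del masks["csf"]
        with pytest.raises(ValueError):
            run_rt_pipeline(np.ones(shape), masks)

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        shape = (8, 8, 4)
        ratio = rng.uniform(0, 3.0, shape)
        nawm = np.zeros(shape, dtype=bool)
        nawm[:2, :2, :] = True
        masks = self._masks(shape, nawm)
        r1 = run_rt_pipeline(ratio, masks)
        r2 = run_rt_pipeline(ratio, masks)
        assert np.array_equal(r1.target_mask, r2.target_mask)
        assert r1.nawm_mean == r2.nawm_mean
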