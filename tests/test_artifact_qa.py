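"""Halo segmentation, intensity profiles, and difference maps."""

import numpy as np
import pytest

from petacpurify.artifact_qa import (
    default_hot_mask,
    detect_halo,
    intensity_profile,
    relative_difference_map,
)
from petacpurify.grid import VoxelGrid
from petacpurify.phantoms import inject_halo, simulate_pair

from .oracles import oracle_relative_difference


class TestDetectHalo:
    def test_no_subthreshold_voxels_gives_empty_list(self):
        vol = VoxelGrid(np.full((16, 16, 16), 5.0, np.float32))
        hot = np.zeros(vol.shape, bool)
        hot[8, 8, 8] = True
        body = np.ones(vol.shape, bool)
        assert detect_halo(vol, hot, body_mask=body) == []

    def test_recovers_injected_void_within_ten_percent(self, phantom_small):
        pair = simulate_pair(phantom_small, "none", noise_scale=0.05, seed=13)
        grid = pair.ct_ac
        center = np.argwhere(phantom_small.organ_masks["bladder"]).mean(axis=0)
        corrupted, params = inject_halo(grid, tuple(center), 18.0, 32.0, 1.0)
        segs = detect_halo(corrupted, phantom_small.organ_masks["bladder"],
                           body_mask=phantom_small.organ_masks["body"])
        assert segs, "injected full-suppression halo not detected"
        assert segs[0].voxel_count == pytest.approx(params["shell_voxels"], rel=0.10)

    def test_clean_case_has_no_halo(self, phantom_small, noisy_pair):
        segs = detect_halo(noisy_pair.ct_ac, phantom_small.organ_masks["bladder"],
                           body_mask=phantom_small.organ_masks["body"])
        assert segs == []

    def test_detected_count_monotone_in_suppression(self, phantom_small):
        pair = simulate_pair(phantom_small, "none", noise_scale=0.05, seed=17)
        center = np.argwhere(phantom_small.organ_masks["bladder"]).mean(axis=0)
        counts = []
        for s in (0.5, 0.8, 0.95, 1.0):
            corrupted, _ = inject_halo(pair.ct_ac, tuple(center), 18.0, 30.0, s)
            segs = detect_halo(corrupted, phantom_small.organ_masks["bladder"],
                               body_mask=phantom_small.organ_masks["body"])
            counts.append(segs[0].voxel_count if segs else 0)
        assert counts == sorted(counts)

    def test_hot_mask_default_selects_hot_organs(self, phantom_small,
                                                 clean_pair_noiseless):
        hot = default_hot_mask(clean_pair_noiseless.ct_ac,
                               phantom_small.organ_masks["body"])
        organs = (phantom_small.organ_masks["bladder"]
                  | phantom_small.organ_masks["left_kidney"]
                  | phantom_small.organ_masks["right_kidney"])
        # detected hot voxels overwhelmingly belong to the true hot organs
        assert (hot & organs).sum() / hot.sum() > 0.9


class TestIntensityProfile:
    def test_constant_volume_flat_profile(self):
        vol = VoxelGrid(np.full((12, 12, 12), 3.5, np.float32))
        prof = intensity_profile(vol, (1, 1, 1), (10, 10, 10), 25)
        assert np.allclose(prof[:, 1], 3.5)
        assert prof[0, 0] == 0.0

    def test_swapped_endpoints_reverse_the_profile(self, noisy_pair):
        a = intensity_profile(noisy_pair.ct_ac, (3, 4, 5), (25, 20, 30), 40)
        b = intensity_profile(noisy_pair.ct_ac, (25, 20, 30), (3, 4, 5), 40)
        assert np.allclose(a[:, 1], b[::-1, 1], atol=1e-10)
        assert np.allclose(a[:, 0], b[:, 0])

    def test_profile_dips_inside_halo_but_not_in_clean_ref(self, phantom_small,
                                                           halo_pair):
        center = np.argwhere(phantom_small.organ_masks["bladder"]).mean(axis=0)
        start = (0.0, center[1], center[2])
        end = (phantom_small.activity.shape[0] - 1.0, center[1], center[2])
        corrupted = intensity_profile(halo_pair.ct_ac, start, end, 120)
        clean = intensity_profile(halo_pair.clean_ref, start, end, 120)
        solid = clean[:, 1] > 0.5  # positions inside solid tissue/organ
        assert corrupted[solid, 1].min() < 0.5 * clean[solid, 1].min()

    def test_endpoint_outside_grid_rejected(self, noisy_pair):
        with pytest.raises(ValueError, match="outside"):
            intensity_profile(noisy_pair.ct_ac, (0, 0, 0), (500, 0, 0), 10)


class TestRelativeDifferenceMap:
    def test_identical_volumes_give_zero(self, noisy_pair):
        diff, valid = relative_difference_map(noisy_pair.ct_ac, noisy_pair.ct_ac,
                                              floor=0.01)
        assert np.all(diff.data == 0)

    def test_uniform_scaling_gives_uniform_percent(self):
        b = VoxelGrid(np.full((8, 8, 8), 2.0, np.float32))
        a = b.with_data(b.data * 1.1)
        diff, valid = relative_difference_map(a, b, floor=0.5)
        assert np.allclose(diff.data, 10.0, atol=1e-4)
        assert valid.all()

    def test_matches_loop_oracle(self, rng):
        a = VoxelGrid(rng.random((6, 6, 6)).astype(np.float32))
        b = VoxelGrid(rng.random((6, 6, 6)).astype(np.float32))
        diff, _ = relative_difference_map(a, b, floor=0.2)
        oracle = oracle_relative_difference(a.data, b.data, 0.2)
        assert np.abs(diff.data - oracle).max() < 1e-12

    def test_pure_function_of_inputs(self, rng):
        a = VoxelGrid(rng.random((5, 5, 5)).astype(np.float32))
        b = VoxelGrid(rng.random((5, 5, 5)).astype(np.float32))
        d1, v1 = relative_difference_map(a, b, floor=0.1)
        d2, v2 = relative_difference_map(a, b, floor=0.1)
        assert np.array_equal(d1.data, d2.data)
        assert np.array_equal(v1, v2)
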