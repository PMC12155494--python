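"""Simulator physics, phantom invariants, and artifact-injection ground truth."""

import math

import numpy as np
import pytest

from petacpurify.grid import VoxelGrid
from petacpurify.phantoms import (
    GeometryError,
    inject_halo,
    inject_motion,
    inject_truncation,
    make_phantom,
    simulate_dataset,
    simulate_pair,
    survival_map,
    body_radius_mm,
    _survival_map_dense,
)
from petacpurify.metrics import EvaluationMask, compute_case_metrics


class TestMakePhantom:
    def test_deterministic_for_fixed_seed(self):
        a = make_phantom(5, grid_shape=(32, 32, 40))
        b = make_phantom(5, grid_shape=(32, 32, 40))
        assert np.array_equal(a.activity.data, b.activity.data)
        assert np.array_equal(a.mu.data, b.mu.data)
        for name in a.organ_masks:
            assert np.array_equal(a.organ_masks[name], b.organ_masks[name])

    def test_organ_to_background_ratio(self, phantom_small):
        act = phantom_small.activity.data
        soft = act[phantom_small.soft_tissue_mask].mean()
        for organ in ("bladder", "left_kidney", "right_kidney"):
            assert act[phantom_small.organ_masks[organ]].mean() >= 10 * soft

    def test_masks_and_mu_invariants(self, phantom_small):
        masks = phantom_small.organ_masks
        body = masks["body"]
        for name, m in masks.items():
            if name != "body":
                assert not np.any(m & ~body)
        mu = phantom_small.mu.data
        assert np.all(mu[~body] == 0)
        assert mu.min() >= 0 and mu.max() <= 0.2

    def test_seed_changes_organ_centroids(self):
        a = make_phantom(1, grid_shape=(32, 32, 40), geometry_jitter=0.1)
        b = make_phantom(2, grid_shape=(32, 32, 40), geometry_jitter=0.1)
        ca = np.argwhere(a.organ_masks["bladder"]).mean(axis=0)
        cb = np.argwhere(b.organ_masks["bladder"]).mean(axis=0)
        assert not np.allclose(ca, cb, atol=1e-6)

    def test_grid_too_small_raises(self):
        with pytest.raises((GeometryError, ValueError)):
            make_phantom(1, grid_shape=(8, 8, 8))


class TestSurvivalMap:
    def test_zero_attenuation_gives_unity(self):
        mu = VoxelGrid(np.zeros((20, 20, 8), np.float32))
        S = survival_map(mu, n_angles=6)
        assert np.all(S.data == 1.0)

    def test_range_and_positivity(self, phantom_small):
        S = survival_map(phantom_small.mu)
        assert S.data.min() > 0
        assert S.data.max() <= 1.0

    def test_slab_closed_form(self):
        """Uniform slab, single perpendicular ray: S = exp(-mu * t)."""
        mu_val, half = 0.096, (12, 36)
        data = np.zeros((48, 48, 8), np.float32)
        data[:, half[0]:half[1], :] = mu_val
        g = VoxelGrid(data, (4.07, 4.07, 3.0))
        S = survival_map(g, n_angles=1, step_mm=1.0)
        t_cm = (half[1] - half[0]) * 4.07 / 10.0
        expected = math.exp(-mu_val * t_cm)
        assert S.data[24, 24, 4] == pytest.approx(expected, rel=5e-3)

    def test_pointwise_monotone_in_mu(self, phantom_small):
        S = survival_map(phantom_small.mu)
        S2 = survival_map(phantom_small.mu.with_data(phantom_small.mu.data * 1.5))
        assert np.all(S2.data <= S.data + 1e-7)

    def test_sparse_operator_matches_dense_reference(self, phantom_small):
        a = survival_map(phantom_small.mu, n_angles=12)
        b = _survival_map_dense(phantom_small.mu, n_angles=12)
        assert np.abs(a.data - b.data).max() < 1e-6

    def test_rejects_negative_mu(self):
        with pytest.raises(ValueError, match="negative"):
            survival_map(VoxelGrid(np.full((16, 16, 4), -0.1, np.float32)))


class TestSimulatePair:
    def test_noiseless_artifact_free_correction_is_exact(self, phantom_small,
                                                         clean_pair_noiseless):
        act = phantom_small.activity.data
        err = np.abs(clean_pair_noiseless.ct_ac.data - act).max() / act.max()
        assert err < 1e-6
        err_clean = np.abs(clean_pair_noiseless.clean_ref.data - act).max() / act.max()
        assert err_clean < 1e-6

    def test_attenuation_only_removes_counts(self, clean_pair_noiseless):
        assert np.all(clean_pair_noiseless.non_ac.data
                      <= clean_pair_noiseless.clean_ref.data + 1e-6)

    def test_reproducible_bit_for_bit(self, phantom_small):
        a = simulate_pair(phantom_small, "halo", noise_scale=0.05, seed=9)
        b = simulate_pair(phantom_small, "halo", noise_scale=0.05, seed=9)
        assert np.array_equal(a.non_ac.data, b.non_ac.data)
        assert np.array_equal(a.ct_ac.data, b.ct_ac.data)

    def test_halo_case_has_zero_shell_clean_ref_does_not(self, phantom_small):
        pair = simulate_pair(phantom_small, "halo", noise_scale=0.0, seed=3,
                             artifact_params=None)
        shells = pair.artifact_params["shells"]
        bladder = next(s for s in shells if s["organ"] == "bladder")
        grid = pair.ct_ac
        center_mm = grid.index_to_mm(bladder["center_voxel"])
        cx, cy, cz = (g - c for g, c in zip(grid.voxel_centers_mm(), center_mm))
        d2 = cx[:, None, None]**2 + cy[None, :, None]**2 + cz[None, None, :]**2
        shell = (d2 >= bladder["r_inner_mm"]**2) & (d2 <= bladder["r_outer_mm"]**2)
        suppression = bladder["suppression"]
        assert np.all(pair.ct_ac.data[shell]
                      <= (1 - suppression) * pair.clean_ref.data[shell] + 1e-5)
        assert pair.clean_ref.data[shell].max() > 0.1

    def test_every_artifact_degrades_reference(self, phantom_small):
        """MAE(ct_ac, clean_ref) must exceed the artifact-free value at the
        same seed and noise — the premise that purification can work."""
        body = EvaluationMask(phantom_small.organ_masks["body"])
        def mae(pair):
            return compute_case_metrics(pair.ct_ac, pair.clean_ref, body).mae
        base = mae(simulate_pair(phantom_small, "none", noise_scale=0.05, seed=5))
        for artifact in ("halo", "motion", "truncation"):
            corrupted = mae(simulate_pair(phantom_small, artifact,
                                          noise_scale=0.05, seed=5))
            assert corrupted > base

    def test_motion_error_concentrates_at_lung_interface(self, phantom_small):
        none = simulate_pair(phantom_small, "none", noise_scale=0.0, seed=5)
        moved = simulate_pair(phantom_small, "motion", noise_scale=0.0, seed=5,
                              artifact_params={"shift_voxels": (0, 0, 3)})
        lungs = phantom_small.organ_masks["lungs"]
        zs = np.where(lungs.any(axis=(0, 1)))[0]
        slab = np.zeros(lungs.shape, bool)
        slab[:, :, max(zs.min() - 4, 0):zs.min() + 4] = True
        slab &= phantom_small.organ_masks["body"]
        err_moved = np.abs(moved.ct_ac.data - moved.clean_ref.data)[slab].mean()
        err_none = np.abs(none.ct_ac.data - none.clean_ref.data)[slab].mean()
        assert err_moved > err_none


class TestInjectHalo:
    def test_zero_suppression_is_identity(self, clean_pair_noiseless):
        out, params = inject_halo(clean_pair_noiseless.ct_ac, (16, 16, 8),
                                  10.0, 25.0, suppression=0.0)
        assert np.array_equal(out.data, clean_pair_noiseless.ct_ac.data)
        assert params["shell_voxels"] > 0

    def test_full_suppression_zeroes_shell(self, clean_pair_noiseless):
        out, params = inject_halo(clean_pair_noiseless.ct_ac, (16, 16, 8),
                                  10.0, 25.0, suppression=1.0)
        assert params["shell_voxels"] > 0
        changed = out.data != clean_pair_noiseless.ct_ac.data
        assert np.all(out.data[changed] == 0)

    def test_shell_count_matches_brute_force(self, clean_pair_noiseless):
        grid = clean_pair_noiseless.ct_ac
        center = (15.0, 17.0, 9.0)
        r_in, r_out = 8.0, 22.0
        _, params = inject_halo(grid, center, r_in, r_out, 0.5)
        count = 0
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                for k in range(grid.shape[2]):
                    pos = (np.array([i, j, k]) - np.array(center)) * grid.spacing_mm
                    d = math.sqrt((pos**2).sum())
                    if r_in <= d <= r_out:
                        count += 1
        assert params["shell_voxels"] == count

    def test_shell_outside_grid_raises(self, clean_pair_noiseless):
        with pytest.raises(ValueError, match="outside"):
            inject_halo(clean_pair_noiseless.ct_ac, (200, 200, 200), 1.0, 2.0, 1.0)


class TestInjectMotionTruncation:
    def test_zero_shift_identity(self, phantom_small):
        out = inject_motion(phantom_small.mu, (0, 0, 0))
        assert np.array_equal(out.data, phantom_small.mu.data)

    def test_shift_inverts_in_interior(self, phantom_small):
        fwd = inject_motion(phantom_small.mu, (0, 0, 2))
        back = inject_motion(fwd, (0, 0, -2))
        inner = (slice(None), slice(None), slice(4, -4))
        assert np.array_equal(back.data[inner], phantom_small.mu.data[inner])

    def test_shift_changes_survival_on_body_voxels(self, phantom_small):
        S = survival_map(phantom_small.mu)
        S2 = survival_map(inject_motion(phantom_small.mu, (0, 1, 3)))
        body = phantom_small.organ_masks["body"]
        frac = np.mean(np.abs(S.data - S2.data)[body] > 1e-4)
        assert frac >= 0.01

    def test_truncation_identity_beyond_body(self, phantom_small):
        r = body_radius_mm(phantom_small)
        out = inject_truncation(phantom_small.mu, r + 5)
        assert np.array_equal(out.data, phantom_small.mu.data)

    def test_truncation_matches_brute_force_set(self, phantom_small):
        mu = phantom_small.mu
        fov = 0.7 * body_radius_mm(phantom_small)
        out = inject_truncation(mu, fov)
        nx, ny, nz = mu.shape
        sx, sy, _ = mu.spacing_mm
        zeroed = (mu.data != 0) & (out.data == 0)
        expected = np.zeros(mu.shape, bool)
        for i in range(nx):
            for j in range(ny):
                r = math.hypot((i + 0.5) * sx - nx * sx / 2,
                               (j + 0.5) * sy - ny * sy / 2)
                if r > fov:
                    expected[i, j, :] = mu.data[i, j, :] != 0
        assert np.array_equal(zeroed, expected)
        assert (out.data != 0).sum() < (mu.data != 0).sum()


class TestSimulateDataset:
    def test_cohort_composition_and_determinism(self):
        cases = simulate_dataset(8, 2, artifact_fraction=0.25, seed=3,
                                 grid_shape=(32, 32, 40))
        assert len(cases) == 10
        train = [c for c in cases if c.split == "train"]
        test = [c for c in cases if c.split == "test"]
        assert len(train) == 8 and len(test) == 2
        assert sum(c.artifact_label != "none" for c in train) == 2
        assert all(c.artifact_label == "none" for c in test)
        again = simulate_dataset(8, 2, artifact_fraction=0.25, seed=3,
                                 grid_shape=(32, 32, 40))
        for a, b in zip(cases, again):
            assert a.case_id == b.case_id
            assert np.array_equal(a.ct_ac.data, b.ct_ac.data)
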