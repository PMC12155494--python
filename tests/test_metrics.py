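"""Metric kernels against brute-force oracles and their exact identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petacpurify.grid import VoxelGrid
from petacpurify.metrics import (
    EvaluationMask,
    auto_body_mask,
    compute_case_metrics,
    mean_over_voi,
    ssim3d,
)

from .oracles import (
    oracle_basic_metrics,
    oracle_mean_over_voi,
    oracle_psnr,
    oracle_ssim_map,
)


def _pair(rng, shape=(6, 6, 6)):
    a = (rng.random(shape) + 0.1).astype(np.float32)
    b = (rng.random(shape) + 0.1).astype(np.float32)
    return VoxelGrid(a), VoxelGrid(b)


class TestOracleEquivalence:
    def test_basic_metrics_match_loop_oracle(self, rng):
        for _ in range(20):
            pred, ref = _pair(rng)
            mask = rng.random(pred.shape) > 0.3
            if not mask.any():
                continue
            floor = 0.3
            cm = compute_case_metrics(
                pred, ref, EvaluationMask(mask, relative_floor=floor)
            )
            oracle = oracle_basic_metrics(pred.data, ref.data, mask, floor)
            for key in ("me", "mae", "rmse", "re_pct", "are_pct"):
                assert getattr(cm, key) == pytest.approx(oracle[key], rel=1e-10)
            assert cm.n_voxels_evaluated == oracle["n"]
            assert cm.n_voxels_relative == oracle["n_rel"]

    def test_clamp_floor_mode_matches_loop_oracle(self, rng):
        """The clamped-denominator variant keeps near-zero-reference voxels
        in the relative sums (photopenic voids must register as error)."""
        for _ in range(10):
            pred, ref = _pair(rng)
            ref.data[ref.data < 0.3] = 0.0  # voids
            mask = np.ones(pred.shape, bool)
            cm = compute_case_metrics(
                pred, ref, EvaluationMask(mask, relative_floor=0.2,
                                          floor_mode="clamp")
            )
            oracle = oracle_basic_metrics(pred.data, ref.data, mask, 0.2,
                                          floor_mode="clamp")
            assert cm.are_pct == pytest.approx(oracle["are_pct"], rel=1e-10)
            assert cm.re_pct == pytest.approx(oracle["re_pct"], rel=1e-10)
            assert cm.n_voxels_relative == oracle["n"]

    def test_ssim_matches_window_oracle(self, rng):
        pred, ref = _pair(rng, shape=(7, 6, 8))
        L = float(ref.data.max() - ref.data.min())
        ours = ssim3d(pred.data, ref.data, data_range=L)
        oracle = oracle_ssim_map(pred.data, ref.data, L)
        assert np.max(np.abs(ours - oracle)) < 1e-10

    def test_psnr_matches_oracle(self, rng):
        pred, ref = _pair(rng)
        mask = np.ones(pred.shape, bool)
        cm = compute_case_metrics(pred, ref, EvaluationMask(mask, relative_floor=0.1))
        assert cm.psnr == pytest.approx(oracle_psnr(pred.data, ref.data, mask), rel=1e-10)

    def test_mean_over_voi_matches_oracle(self, rng):
        vol, _ = _pair(rng)
        voi = rng.random(vol.shape) > 0.5
        assert mean_over_voi(vol, voi) == pytest.approx(
            oracle_mean_over_voi(vol.data, voi), rel=1e-12
        )

    def test_ssim_cross_checks_reference_library(self, rng):
        """Interior voxels agree with scikit-image's Gaussian-window SSIM
        (border handling differs by design, so compare away from edges)."""
        skimage_metrics = pytest.importorskip("skimage.metrics")
        pred, ref = _pair(rng, shape=(16, 16, 16))
        L = float(ref.data.max() - ref.data.min())
        ours = ssim3d(pred.data, ref.data, data_range=L)
        _, ref_map = skimage_metrics.structural_similarity(
            pred.data.astype(np.float64), ref.data.astype(np.float64),
            data_range=L, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, full=True,
        )
        inner = (slice(6, 10),) * 3
        assert np.allclose(ours[inner], ref_map[inner], atol=5e-4)


class TestMetricIdentities:
    def test_identical_images(self, rng):
        vol, _ = _pair(rng)
        cm = compute_case_metrics(vol, vol, EvaluationMask(np.ones(vol.shape, bool),
                                                           relative_floor=0.05))
        assert cm.me == cm.mae == cm.rmse == 0
        assert cm.re_pct == cm.are_pct == 0
        assert cm.ssim == pytest.approx(1.0)
        assert cm.psnr is None and cm.psnr_infinite

    @pytest.mark.parametrize("c", [0.25, -0.25])
    def test_constant_shift(self, rng, c):
        _, ref = _pair(rng)
        pred = ref.with_data(ref.data + c)
        cm = compute_case_metrics(pred, ref, EvaluationMask(np.ones(ref.shape, bool),
                                                            relative_floor=0.05))
        assert cm.me == pytest.approx(c, rel=1e-6)
        assert cm.mae == pytest.approx(abs(c), rel=1e-6)
        assert cm.rmse == pytest.approx(abs(c), rel=1e-6)

    def test_ordering_chain_and_are_dominance(self, rng):
        for _ in range(30):
            pred, ref = _pair(rng)
            cm = compute_case_metrics(pred, ref,
                                      EvaluationMask(np.ones(ref.shape, bool),
                                                     relative_floor=0.2))
            assert abs(cm.me) <= cm.mae + 1e-12
            assert cm.mae <= cm.rmse + 1e-12
            assert cm.are_pct >= abs(cm.re_pct) - 1e-9

    def test_ssim_symmetry(self, rng):
        a, b = _pair(rng, shape=(8, 8, 8))
        L = float(max(a.data.max(), b.data.max()) - min(a.data.min(), b.data.min()))
        assert np.allclose(ssim3d(a.data, b.data, L), ssim3d(b.data, a.data, L))

    def test_ssim_affine_rescale_invariance(self, rng):
        """Scaling both inputs by a common positive factor leaves SSIM
        unchanged when the dynamic range tracks the data."""
        a, b = _pair(rng, shape=(8, 8, 8))
        L = float(b.data.max() - b.data.min())
        s = 3.7
        m1 = ssim3d(a.data, b.data, L)
        m2 = ssim3d(s * a.data, s * b.data, s * L)
        assert np.allclose(m1, m2, atol=1e-6)  # float rounding only

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        """Voxel-averaged metrics ignore spatial arrangement: permuting both
        grids identically leaves ME/MAE/RMSE/RE/ARE unchanged."""
        rng = np.random.default_rng(seed)
        pred, ref = _pair(rng, shape=(5, 5, 5))
        perm = rng.permutation(pred.data.size)
        mask = EvaluationMask(np.ones(pred.shape, bool), relative_floor=0.2)
        cm1 = compute_case_metrics(pred, ref, mask)
        p2 = VoxelGrid(pred.data.ravel()[perm].reshape(pred.shape))
        r2 = VoxelGrid(ref.data.ravel()[perm].reshape(ref.shape))
        cm2 = compute_case_metrics(p2, r2, mask)
        for key in ("me", "mae", "rmse", "re_pct", "are_pct"):
            assert getattr(cm1, key) == pytest.approx(getattr(cm2, key), rel=1e-9)


class TestErrorsAndVOI:
    def test_empty_relative_set_is_an_error(self, rng):
        pred, ref = _pair(rng)
        with pytest.raises(ValueError, match="relative"):
            compute_case_metrics(pred, ref,
                                 EvaluationMask(np.ones(ref.shape, bool),
                                                relative_floor=1e6))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            EvaluationMask(np.zeros((4, 4, 4), bool))

    def test_voi_relative_error(self, rng):
        _, ref = _pair(rng)
        pred = ref.with_data(ref.data * 1.1)
        voi = np.zeros(ref.shape, bool)
        voi[2:4, 2:4, 2:4] = True
        cm = compute_case_metrics(pred, ref,
                                  EvaluationMask(np.ones(ref.shape, bool),
                                                 relative_floor=0.05), voi=voi)
        assert cm.re_voi_pct == pytest.approx(10.0, rel=1e-5)

    def test_constant_voi_mean(self):
        vol = VoxelGrid(np.full((4, 4, 4), 2.5, np.float32))
        voi = np.zeros(vol.shape, bool)
        voi[1, 2, 3] = True
        assert mean_over_voi(vol, voi) == pytest.approx(2.5)
        with pytest.raises(ValueError, match="empty"):
            mean_over_voi(vol, np.zeros(vol.shape, bool))

    def test_auto_body_mask_fills_photopenic_holes(self, rng):
        data = np.zeros((16, 16, 16), np.float32)
        data[3:13, 3:13, 3:13] = 1.0
        data[7:9, 7:9, 7:9] = 0.0  # interior void must stay inside the body
        mask = auto_body_mask(VoxelGrid(data))
        assert mask[8, 8, 8]
        assert not mask[0, 0, 0]
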