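"""Voxel-wise and VOI-based image-quality metrics.

The evaluation suite used throughout the package: signed mean error (ME),
mean absolute error (MAE), voxel-wise relative error (RE%), absolute
relative error (ARE%), VOI-level relative error, root mean square error
(RMSE), plus the perceptual pair SSIM and PSNR.  All sums run over an
explicit evaluation mask (by default the body, so empty air does not dilute
the averages), accumulate in float64, and carry the input's intensity units.

Relative metrics divide by the reference, so they are restricted to voxels
where the reference is at least ``relative_floor`` — otherwise near-zero
reference voxels dominate the mean.  The floor defaults to 1% of the
reference's 99th-percentile value inside the mask and is reported with the
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid, require_same_geometry

#: SSIM regularization constants as fractions of the dynamic range L:
#: C1 = (K1*L)^2, C2 = (K2*L)^2 — the standard reference parameterization.
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_SIGMA = 1.5
SSIM_RADIUS = 5  # 11^3 window support


@dataclass
class EvaluationMask:
    """The voxel set entering the metric sums.

    ``relative_floor`` (same units as the reference) gates the voxels used
    for RE%/ARE%; if None it is derived per case as 1% of the reference's
    99th percentile inside the mask.
    """

    mask: np.ndarray
    relative_floor: Optional[float] = None
    #: 'exclude' drops voxels with reference < floor from RE%/ARE% (clean
    #: evaluation semantics); 'clamp' keeps every mask voxel and clamps the
    #: denominator at the floor — the right choice when scoring references
    #: that may contain photopenic voids, which 'exclude' would silently
    #: remove from the error sums.
    floor_mode: str = "exclude"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("evaluation mask is empty")
        if self.relative_floor is not None and self.relative_floor <= 0:
            raise ValueError("relative_floor must be positive")
        if self.floor_mode not in ("exclude", "clamp"):
            raise ValueError("floor_mode must be 'exclude' or 'clamp'")


@dataclass
class CaseMetrics:
    """Per-case metric values, in the reference's intensity units."""

    case_id: str
    me: float
    mae: float
    re_pct: float
    are_pct: float
    rmse: float
    ssim: float
    psnr: Optional[float]  # dB; None encodes an infinite PSNR (MSE = 0)
    n_voxels_evaluated: int
    re_voi_pct: Optional[float] = None
    relative_floor: float = 0.0
    n_voxels_relative: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def psnr_infinite(self) -> bool:
        return self.psnr is None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "me": self.me,
            "mae": self.mae,
            "re_pct": self.re_pct,
            "are_pct": self.are_pct,
            "re_voi_pct": self.re_voi_pct,
            "rmse": self.rmse,
            "ssim": self.ssim,
            "psnr": self.psnr,
            "psnr_infinite": self.psnr_infinite,
            "n_voxels_evaluated": self.n_voxels_evaluated,
            "n_voxels_relative": self.n_voxels_relative,
            "relative_floor": self.relative_floor,
            **self.extras,
        }


def auto_body_mask(grid: VoxelGrid, threshold_fraction: float = 0.05) -> np.ndarray:
    """Derive a body mask: voxels above a fraction of the 99th-percentile
    intensity, with interior holes filled (so photopenic artifact voids stay
    inside the mask)."""
    data = grid.data
    thr = threshold_fraction * np.percentile(data, 99)
    mask = ndimage.binary_fill_holes(data > thr)
    if not mask.any():
        raise ValueError("no body mask derivable: volume appears empty")
    return mask


def mean_over_voi(volume: VoxelGrid, voi: np.ndarray) -> float:
    """Arithmetic mean of ``volume`` over the VOI voxels."""
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != volume.shape:
        raise ValueError("VOI shape does not match the volume")
    if not voi.any():
        raise ValueError("VOI is empty")
    return float(volume.data[voi].astype(np.float64).mean())


def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _local_mean(volume: np.ndarray, kernel: np.ndarray, norm: np.ndarray) -> np.ndarray:
    out = volume
    for axis in range(3):
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="constant", cval=0.0)
    return out / norm


def ssim3d(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float,
    sigma: float = SSIM_SIGMA,
    radius: int = SSIM_RADIUS,
) -> np.ndarray:
    """Voxel-wise 3D SSIM map with a Gaussian window.

    Local statistics use a separable Gaussian window (sigma, support
    ``2*radius+1`` per axis) truncated at the volume borders: window weights
    falling outside the volume are renormalized away rather than padded in,
    so border voxels are compared over their in-volume neighborhood only.
    Weighted (non-sample) covariances, the standard reference formulation.
    """
    if a.shape != b.shape:
        raise ValueError("SSIM inputs must share shape")
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    kernel = _gaussian_kernel_1d(sigma, radius)
    norm = np.ones(a.shape, dtype=np.float64)
    for axis in range(3):
        norm = ndimage.correlate1d(norm, kernel, axis=axis, mode="constant", cval=0.0)

    mu_a = _local_mean(a, kernel, norm)
    mu_b = _local_mean(b, kernel, norm)
    var_a = _local_mean(a * a, kernel, norm) - mu_a**2
    var_b = _local_mean(b * b, kernel, norm) - mu_b**2
    cov = _local_mean(a * b, kernel, norm) - mu_a * mu_b

    # floor the range so two identical constant images still score 1
    data_range = max(data_range, np.finfo(np.float64).tiny)
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return num / den


def compute_case_metrics(
    predicted: VoxelGrid,
    reference: VoxelGrid,
    mask: Optional[EvaluationMask] = None,
    voi: Optional[np.ndarray] = None,
    case_id: str = "",
    include_ssim: bool = True,
) -> CaseMetrics:
    """All metrics for one (predicted, reference) volume pair.

    ME/MAE/RMSE/SSIM/PSNR run over ``mask`` (default: auto body mask of the
    reference); RE%/ARE% over ``mask`` intersected with
    ``reference >= relative_floor``; the VOI-level relative error over the
    optional ``voi`` grid.  An infinite PSNR (identical images) is encoded
    as ``psnr=None``.
    """
    require_same_geometry(predicted, reference)
    if mask is None:
        mask = EvaluationMask(auto_body_mask(reference))
    if mask.mask.shape != reference.shape:
        raise ValueError("mask shape does not match the volumes")

    m = mask.mask
    p = predicted.data[m].astype(np.float64)
    r = reference.data[m].astype(np.float64)
    diff = p - r

    me = float(diff.mean())
    mae = float(np.abs(diff).mean())
    rmse = float(math.sqrt((diff**2).mean()))

    floor = mask.relative_floor
    if floor is None:
        floor = max(0.01 * float(np.percentile(r, 99)), np.finfo(np.float64).tiny)
    if mask.floor_mode == "clamp":
        rel_sel = np.ones_like(r, dtype=bool)
        rel = diff / np.maximum(r, floor)
    else:
        rel_sel = r >= floor
        if not rel_sel.any():
            raise ValueError(
                f"no voxels with reference >= relative_floor ({floor:g}); "
                "relative metrics undefined"
            )
        rel = diff[rel_sel] / r[rel_sel]
    re_pct = float(rel.mean() * 100.0)
    are_pct = float(np.abs(rel).mean() * 100.0)

    re_voi_pct = None
    if voi is not None:
        ref_voi = mean_over_voi(reference, voi)
        if ref_voi == 0:
            raise ValueError("VOI mean of the reference is zero; RE_VOI undefined")
        re_voi_pct = float((mean_over_voi(predicted, voi) - ref_voi) / ref_voi * 100.0)

    data_range = float(r.max() - r.min())
    if include_ssim:
        ssim_map = ssim3d(predicted.data, reference.data, data_range=data_range)
        ssim = float(ssim_map[m].mean())
    else:
        ssim = float("nan")

    mse = float((diff**2).mean())
    if mse == 0.0:
        psnr = None
    else:
        psnr = float(10.0 * math.log10(data_range**2 / mse)) if data_range > 0 else None

    return CaseMetrics(
        case_id=case_id,
        me=me,
        mae=mae,
        re_pct=re_pct,
        are_pct=are_pct,
        rmse=rmse,
        ssim=ssim,
        psnr=psnr,
        n_voxels_evaluated=int(m.sum()),
        re_voi_pct=re_voi_pct,
        relative_floor=float(floor),
        n_voxels_relative=int(rel_sel.sum()),
    )
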