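"""Synthetic paired non-AC / CT-AC whole-body phantom simulator.

This module stands in for a clinical PSMA PET/CT cohort.  Each phantom is a
desk-scale whole-body-like subject: an elliptic-cylinder torso of soft tissue
(mu = 0.096 cm^-1 at 511 keV) with two ellipsoidal lungs (mu = 0.03 cm^-1),
an optional cortical-bone rim (mu = 0.15 cm^-1), and three intensely hot
urinary-tract organs — two kidneys and a bladder — whose activity exceeds the
soft-tissue background by more than an order of magnitude, emulating the
extreme organ-to-background ratio of renally excreted tracers.

The forward model is image-domain PET physics reduced to its attenuation
essence: both annihilation photons must traverse the full line of response,
so the detection probability of a voxel is the angle-average of
``exp(-integral of mu along the whole line)`` over in-plane lines
(:func:`survival_map`).  A non-AC image is the activity map multiplied by
this survival factor (plus scaled-Poisson counting noise); an attenuation
corrected image divides the survival factor back out.  Corrupting the
attenuation map used for the *correction* — but never the true forward
model — produces the three reference-image artifact classes the purification
pipeline must catch:

* ``halo``       — photopenic suppression shells around the hot organs
                   (failed scatter correction signature), applied in image
                   space on the corrected image;
* ``motion``     — respiratory misalignment: the correction uses a shifted
                   attenuation map;
* ``truncation`` — the correction's attenuation map is zeroed outside a
                   transaxial field-of-view cylinder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import DEFAULT_SPACING_MM, VoxelGrid, require_same_geometry

# Linear attenuation coefficients at 511 keV, cm^-1
MU_SOFT_TISSUE = 0.096
MU_LUNG = 0.03
MU_BONE = 0.15
MU_MAX = 0.2

# SUV-like activity levels
ACTIVITY_SOFT = 1.0
ACTIVITY_LUNG = 0.3
ACTIVITY_KIDNEY = 15.0
ACTIVITY_BLADDER = 20.0

ARTIFACT_LABELS = ("none", "halo", "motion", "truncation")

#: Default artifact severity ranges (package choices, exposed in config):
#: halo suppression fraction, motion axial shift in voxels, truncation
#: field-of-view as a fraction of the body radius.
HALO_SUPPRESSION_RANGE = (0.8, 1.0)
MOTION_AXIAL_SHIFT_RANGE = (2, 4)
TRUNCATION_FOV_FRACTION_RANGE = (0.6, 0.8)

DEFAULT_GRID_SHAPE = (48, 48, 64)
DEFAULT_NOISE_SCALE = 0.05
DEFAULT_N_ANGLES = 36
S_CORRUPT_FLOOR = 1e-3


class GeometryError(ValueError):
    """The requested grid cannot contain the phantom's organs."""


@dataclass
class PhantomCase:
    """Ground truth for one synthetic subject."""

    case_id: str
    activity: VoxelGrid
    mu: VoxelGrid
    organ_masks: dict[str, np.ndarray]
    artifact_label: str = "none"
    artifact_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        require_same_geometry(self.activity, self.mu)
        body = self.organ_masks["body"]
        for name, mask in self.organ_masks.items():
            if mask.shape != self.activity.shape:
                raise ValueError(f"mask {name!r} has wrong shape")
            if name != "body" and np.any(mask & ~body):
                raise ValueError(f"organ mask {name!r} extends outside the body")
        hot = ("left_kidney", "right_kidney", "bladder")
        for a in range(len(hot)):
            for b in range(a + 1, len(hot)):
                if np.any(self.organ_masks[hot[a]] & self.organ_masks[hot[b]]):
                    raise ValueError("kidney/bladder masks overlap")
        mu = self.mu.data
        if np.any(mu[~body] != 0):
            raise ValueError("mu must be zero outside the body")
        if np.any(mu < 0) or np.any(mu > MU_MAX):
            raise ValueError(f"mu must lie in [0, {MU_MAX}] cm^-1")

    @property
    def soft_tissue_mask(self) -> np.ndarray:
        m = self.organ_masks
        soft = m["body"].copy()
        for name in ("lungs", "left_kidney", "right_kidney", "bladder"):
            soft &= ~m[name]
        return soft


@dataclass
class PairedCase:
    """The (non-AC, CT-AC reference) pair a model trains on.

    ``clean_ref`` is the artifact-free ideal correction, available only for
    synthetic subjects; ``ct_ac`` is the reference the model sees and may be
    artifact-corrupted.
    """

    case_id: str
    non_ac: VoxelGrid
    ct_ac: VoxelGrid
    clean_ref: Optional[VoxelGrid] = None
    artifact_label: str = "none"
    split: Optional[str] = None
    artifact_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.artifact_label not in ARTIFACT_LABELS:
            raise ValueError(f"unknown artifact label {self.artifact_label!r}")
        grids = [self.non_ac, self.ct_ac]
        if self.clean_ref is not None:
            grids.append(self.clean_ref)
        require_same_geometry(*grids)
        if self.split not in (None, "train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")


def _ellipsoid_mask(centers, center_mm, semi_mm) -> np.ndarray:
    x, y, z = centers
    dx = (x[:, None, None] - center_mm[0]) / semi_mm[0]
    dy = (y[None, :, None] - center_mm[1]) / semi_mm[1]
    dz = (z[None, None, :] - center_mm[2]) / semi_mm[2]
    return dx * dx + dy * dy + dz * dz <= 1.0


def _sphere_mask(centers, center_mm, radius_mm) -> np.ndarray:
    return _ellipsoid_mask(centers, center_mm, (radius_mm,) * 3)


def make_phantom(
    seed: int,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    geometry_jitter: float = 0.1,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    bone_shell: bool = True,
    case_id: Optional[str] = None,
) -> PhantomCase:
    """Generate one synthetic subject, deterministically from ``seed``.

    ``geometry_jitter`` is the fractional +/- range applied to organ
    positions, sizes, and activity levels, emulating cohort variability.
    """
    if any(n < 16 for n in grid_shape):
        raise GeometryError(f"grid {grid_shape} too small: each axis must be >= 16")
    if not 0 <= geometry_jitter <= 0.3:
        raise ValueError("geometry_jitter must lie in [0, 0.3]")

    rng = np.random.default_rng(seed)
    jit = lambda: 1.0 + rng.uniform(-geometry_jitter, geometry_jitter)  # noqa: E731

    nx, ny, nz = grid_shape
    sx, sy, sz = spacing_mm
    Lx, Ly, Lz = nx * sx, ny * sy, nz * sz
    template = VoxelGrid(np.zeros(grid_shape, dtype=np.float32), spacing_mm)
    centers = template.voxel_centers_mm()
    cx, cy = Lx / 2, Ly / 2

    # torso: elliptic cylinder spanning the full axial extent
    body_ax = 0.42 * Lx * jit()
    body_ay = 0.36 * Ly * jit()
    x, y = centers[0], centers[1]
    in_plane = ((x[:, None] - cx) / body_ax) ** 2 + ((y[None, :] - cy) / body_ay) ** 2
    body = np.broadcast_to((in_plane <= 1.0)[:, :, None], grid_shape).copy()

    # lungs: two ellipsoids in the thorax (upper axial third)
    lung_z = 0.76 * Lz * jit()
    lung_sep = 0.16 * Lx * jit()
    lung_semi = (0.12 * Lx * jit(), 0.15 * Ly * jit(), 0.13 * Lz * jit())
    lungs = _ellipsoid_mask(centers, (cx - lung_sep, cy, lung_z), lung_semi) | _ellipsoid_mask(
        centers, (cx + lung_sep, cy, lung_z), lung_semi
    )
    lungs &= body

    r_scale = min(Lx, Ly)
    kid_r = 0.062 * r_scale * jit()
    kid_z = 0.46 * Lz * jit()
    kid_dx = 0.15 * Lx * jit()
    kid_y = cy + 0.08 * Ly * jit()
    left_kidney = _sphere_mask(centers, (cx - kid_dx, kid_y, kid_z), kid_r) & body
    right_kidney = _sphere_mask(centers, (cx + kid_dx, kid_y, kid_z), kid_r) & body

    blad_r = 0.085 * r_scale * jit()
    blad_c = (cx + rng.uniform(-1, 1) * geometry_jitter * 8.0, cy - 0.04 * Ly * jit(), 0.18 * Lz * jit())
    bladder = _sphere_mask(centers, blad_c, blad_r) & body
    bladder &= ~(left_kidney | right_kidney)

    for name, mask in (
        ("lungs", lungs),
        ("left_kidney", left_kidney),
        ("right_kidney", right_kidney),
        ("bladder", bladder),
    ):
        if not mask.any():
            raise GeometryError(f"grid {grid_shape} too small to contain organ {name!r}")

    mu = np.zeros(grid_shape, dtype=np.float32)
    mu[body] = MU_SOFT_TISSUE
    mu[lungs] = MU_LUNG
    if bone_shell:
        rim = (in_plane <= 1.0) & (in_plane >= 0.88)
        rim3 = np.broadcast_to(rim[:, :, None], grid_shape) & body & ~lungs
        mu[rim3] = MU_BONE

    activity = np.zeros(grid_shape, dtype=np.float32)
    activity[body] = ACTIVITY_SOFT * jit()
    activity[lungs] = ACTIVITY_LUNG * jit()
    activity[left_kidney] = ACTIVITY_KIDNEY * jit()
    activity[right_kidney] = ACTIVITY_KIDNEY * jit()
    activity[bladder] = ACTIVITY_BLADDER * jit()

    masks = {
        "body": body,
        "lungs": lungs,
        "left_kidney": left_kidney,
        "right_kidney": right_kidney,
        "bladder": bladder,
    }
    case = PhantomCase(
        case_id=case_id or f"phantom_{seed:08d}",
        activity=VoxelGrid(activity, spacing_mm),
        mu=VoxelGrid(mu, spacing_mm),
        organ_masks=masks,
        seed=seed,
    )
    soft_mean = activity[case.soft_tissue_mask].mean()
    for organ in ("left_kidney", "right_kidney", "bladder"):
        if activity[masks[organ]].mean() < 10 * soft_mean:
            raise GeometryError(f"{organ} organ-to-background ratio below 10")
    return case


def _ray_geometry(shape, spacing_mm, n_angles, step):
    """Shared geometry for the ray-marching operators."""
    nx, ny, nz = shape
    sx = spacing_mm[0]
    # pad in-plane so every rotated line stays inside the frame
    P = int(math.ceil(math.hypot(nx, ny))) + 4
    px, py = (P - nx) // 2, (P - ny) // 2
    c = (P - 1) / 2.0
    n_samp = int(math.ceil(P * sx / step)) + 2
    cv = (n_samp - 1) / 2.0
    scale = step / sx  # input pixels advanced per ray sample
    return nx, ny, nz, sx, P, px, py, c, n_samp, cv, scale


class _SurvivalOperator:
    """Precomputed sparse ray-marching operator for one grid geometry.

    For a fixed (shape, spacing, n_angles, step_mm) the sampling pattern of
    every ray is identical across attenuation maps, so the fixed-step,
    bilinearly interpolated line integrals collapse into one sparse matrix
    ``M`` (ray x in-plane voxel); the per-angle interpolation of ray
    integrals back onto voxels is a precomputed linear gather.  The integral
    is interpolated *before* exponentiation, matching the reference
    rotate-resample implementation.
    """

    def __init__(self, shape, spacing_mm, n_angles, step):
        from scipy import sparse

        nx, ny, nz, sx, P, px, py, c, n_samp, cv, scale = _ray_geometry(
            shape, spacing_mm, n_angles, step
        )
        self.shape = shape
        self.P, self.px, self.py = P, px, py
        step_cm = step / 10.0

        u = np.arange(P, dtype=np.float64)
        v = np.arange(n_samp, dtype=np.float64)
        uu, vv = np.meshgrid(u, v, indexing="ij")

        m_rows, m_cols, m_vals = [], [], []
        xpix = np.arange(nx, dtype=np.float64) + px - c
        ypix = np.arange(ny, dtype=np.float64) + py - c
        u0_all = np.empty((n_angles, nx * ny), dtype=np.int64)
        fu_all = np.empty((n_angles, nx * ny), dtype=np.float64)

        for i in range(n_angles):
            theta = i * math.pi / n_angles
            ct, st = math.cos(theta), math.sin(theta)
            # sample positions of ray u at march index v, in padded pixels
            x = c + ct * (uu - c) - st * scale * (vv - cv)
            y = c + st * (uu - c) + ct * scale * (vv - cv)
            x0 = np.floor(x).astype(np.int64)
            y0 = np.floor(y).astype(np.int64)
            fx, fy = x - x0, y - y0
            ray = np.broadcast_to(uu.astype(np.int64) + i * P, x.shape)
            for dx_, dy_, w in (
                (0, 0, (1 - fx) * (1 - fy)),
                (0, 1, (1 - fx) * fy),
                (1, 0, fx * (1 - fy)),
                (1, 1, fx * fy),
            ):
                xi, yi = x0 + dx_, y0 + dy_
                ok = (xi >= 0) & (xi < P) & (yi >= 0) & (yi < P) & (w > 0)
                m_rows.append(ray[ok])
                m_cols.append((xi * P + yi)[ok])
                m_vals.append((w * step_cm)[ok])

            # linear interpolation of ray integrals back onto original voxels
            uf = c + ct * xpix[:, None] + st * ypix[None, :]
            u0 = np.clip(np.floor(uf).astype(np.int64), 0, P - 2)
            u0_all[i] = u0.ravel()
            fu_all[i] = np.clip(uf - u0, 0.0, 1.0).ravel()

        n_rays = n_angles * P
        self.M = sparse.csr_matrix(
            (np.concatenate(m_vals), (np.concatenate(m_rows), np.concatenate(m_cols))),
            shape=(n_rays, P * P),
        )
        self.u0, self.fu = u0_all, fu_all
        self.n_angles = n_angles

    def apply(self, mu_data: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape
        P, px, py = self.P, self.px, self.py
        padded = np.zeros((P, P, nz), dtype=np.float64)
        padded[px : px + nx, py : py + ny] = mu_data
        lines = (self.M @ padded.reshape(P * P, nz)).reshape(self.n_angles, P, nz)
        S = np.zeros((nx * ny, nz), dtype=np.float64)
        for i in range(self.n_angles):
            u0, fu = self.u0[i], self.fu[i][:, None]
            L_vox = (1.0 - fu) * lines[i, u0, :] + fu * lines[i, u0 + 1, :]
            S += np.exp(-L_vox)
        return (S / self.n_angles).reshape(nx, ny, nz)


_OPERATOR_CACHE: dict[tuple, _SurvivalOperator] = {}


def _get_operator(shape, spacing_mm, n_angles, step) -> _SurvivalOperator:
    key = (shape, tuple(round(s, 9) for s in spacing_mm), n_angles, round(step, 9))
    op = _OPERATOR_CACHE.get(key)
    if op is None:
        if len(_OPERATOR_CACHE) > 8:  # bound the cache
            _OPERATOR_CACHE.clear()
        op = _OPERATOR_CACHE[key] = _SurvivalOperator(shape, spacing_mm, n_angles, step)
    return op


def _check_survival_args(mu: VoxelGrid, n_angles: int, step_mm: Optional[float]) -> float:
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if np.any(mu.data < 0):
        raise ValueError("attenuation map has negative voxels")
    sx, sy, _ = mu.spacing_mm
    if not math.isclose(sx, sy, rel_tol=1e-6):
        raise ValueError("survival_map requires isotropic in-plane spacing")
    step = float(step_mm) if step_mm is not None else min(mu.spacing_mm) / 2
    if step <= 0:
        raise ValueError("step_mm must be positive")
    return step


def survival_map(
    mu: VoxelGrid,
    n_angles: int = DEFAULT_N_ANGLES,
    step_mm: Optional[float] = None,
) -> VoxelGrid:
    """Angle-averaged photon-pair survival factor ``S`` in (0, 1].

    ``S(v) = (1/n_angles) * sum_theta exp(-L_theta(v))`` where ``L_theta(v)``
    is the line integral of ``mu`` (cm^-1, path in cm) along the *entire*
    in-plane line through ``v`` at angle ``theta`` — both annihilation
    photons must escape, so the whole line of response counts.  Integrals
    are fixed-step ray marches (bilinearly interpolated samples every
    ``step_mm``), evaluated through a cached sparse operator so that whole
    cohorts sharing one grid geometry pay the geometric setup only once.
    """
    step = _check_survival_args(mu, n_angles, step_mm)
    op = _get_operator(mu.shape, mu.spacing_mm, n_angles, step)
    return mu.with_data(op.apply(mu.data).astype(np.float32))


def _survival_map_dense(
    mu: VoxelGrid,
    n_angles: int = DEFAULT_N_ANGLES,
    step_mm: Optional[float] = None,
) -> VoxelGrid:
    """Reference implementation of :func:`survival_map` by explicit
    rotate-resample-sum per angle (no precomputation); used to cross-check
    the sparse-operator path."""
    step = _check_survival_args(mu, n_angles, step_mm)
    nx, ny, nz, sx, P, px, py, c, n_samp, cv, scale = _ray_geometry(
        mu.shape, mu.spacing_mm, n_angles, step
    )
    mup = np.zeros((P, P, nz), dtype=np.float64)
    mup[px : px + nx, py : py + ny] = mu.data
    xpix = np.arange(nx) + px - c
    ypix = np.arange(ny) + py - c
    zz = np.broadcast_to(np.arange(nz)[None, None, :], (nx, ny, nz)).astype(np.float64)
    S = np.zeros((nx, ny, nz), dtype=np.float64)
    step_cm = step / 10.0
    for i in range(n_angles):
        theta = i * math.pi / n_angles
        ct, st = math.cos(theta), math.sin(theta)
        matrix = np.array(
            [[ct, -st * scale, 0.0], [st, ct * scale, 0.0], [0.0, 0.0, 1.0]]
        )
        offset = np.array([c - ct * c + st * scale * cv, c - st * c - ct * scale * cv, 0.0])
        rot = ndimage.affine_transform(
            mup, matrix, offset=offset, output_shape=(P, n_samp, nz),
            order=1, cval=0.0, prefilter=False,
        )
        line_integral = rot.sum(axis=1) * step_cm  # constant along each ray
        u = c + ct * xpix[:, None] + st * ypix[None, :]
        uu = np.broadcast_to(np.clip(u, 0, P - 1)[:, :, None], (nx, ny, nz))
        L = ndimage.map_coordinates(
            line_integral, [uu.ravel(), zz.ravel()], order=1, mode="nearest"
        ).reshape(nx, ny, nz)
        S += np.exp(-L)
    return mu.with_data((S / n_angles).astype(np.float32))


def inject_halo(
    ct_ac: VoxelGrid,
    center: tuple[float, float, float],
    r_inner_mm: float,
    r_outer_mm: float,
    suppression: float,
) -> tuple[VoxelGrid, dict]:
    """Scale the spherical shell ``[r_inner, r_outer]`` around ``center``
    (voxel coordinates) by ``(1 - suppression)``.

    Returns the corrupted grid and a parameter record including the shell
    voxel count.  ``suppression=1`` produces the photopenic signal void that
    operationally defines a halo.
    """
    if not 0 < r_inner_mm < r_outer_mm:
        raise ValueError("need 0 < r_inner_mm < r_outer_mm")
    if not 0 <= suppression <= 1:
        raise ValueError("suppression must lie in [0, 1]")
    center_mm = ct_ac.index_to_mm(center)
    cx, cy, cz = (g - c for g, c in zip(ct_ac.voxel_centers_mm(), center_mm))
    d2 = (
        cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
    )
    shell = (d2 >= r_inner_mm**2) & (d2 <= r_outer_mm**2)
    n_shell = int(shell.sum())
    if n_shell == 0:
        raise ValueError("halo shell lies entirely outside the grid")
    out = ct_ac.data.copy()
    out[shell] *= 1.0 - suppression
    params = {
        "center_voxel": tuple(float(v) for v in center),
        "r_inner_mm": float(r_inner_mm),
        "r_outer_mm": float(r_outer_mm),
        "suppression": float(suppression),
        "shell_voxels": n_shell,
    }
    return ct_ac.with_data(out), params


def inject_motion(mu: VoxelGrid, shift_voxels: tuple[int, int, int]) -> VoxelGrid:
    """Translate the attenuation map by whole voxels with zero fill.

    Used only to corrupt the map the *correction* sees (PET/CT respiratory
    misalignment); the true forward model always uses the unshifted map.
    """
    shift = tuple(int(s) for s in shift_voxels)
    if any(abs(s) >= n for s, n in zip(shift, mu.shape)):
        raise ValueError(f"shift {shift} exceeds grid extent {mu.shape}")
    out = np.zeros_like(mu.data)
    src = tuple(
        slice(max(0, -s), n - max(0, s)) for s, n in zip(shift, mu.shape)
    )
    dst = tuple(
        slice(max(0, s), n - max(0, -s)) for s, n in zip(shift, mu.shape)
    )
    out[dst] = mu.data[src]
    return mu.with_data(out)


def inject_truncation(mu: VoxelGrid, fov_radius_mm: float) -> VoxelGrid:
    """Zero the attenuation map outside the transaxial cylinder of radius
    ``fov_radius_mm`` centered on the grid axis (CT field-of-view clipping)."""
    if fov_radius_mm <= 0:
        raise ValueError("fov_radius_mm must be positive")
    nx, ny, _ = mu.shape
    sx, sy, _ = mu.spacing_mm
    x, y, _ = mu.voxel_centers_mm()
    r2 = (x[:, None] - nx * sx / 2) ** 2 + (y[None, :] - ny * sy / 2) ** 2
    outside = r2 > fov_radius_mm**2
    out = mu.data.copy()
    out[np.broadcast_to(outside[:, :, None], mu.shape)] = 0.0
    return mu.with_data(out)


def body_radius_mm(phantom: PhantomCase) -> float:
    """Largest in-plane distance of any body voxel from the grid axis."""
    body = phantom.organ_masks["body"]
    nx, ny, _ = body.shape
    sx, sy, _ = phantom.mu.spacing_mm
    x, y, _ = phantom.mu.voxel_centers_mm()
    r2 = (x[:, None] - nx * sx / 2) ** 2 + (y[None, :] - ny * sy / 2) ** 2
    return float(np.sqrt(r2[body.any(axis=2)].max()))


def _mask_centroid(mask: np.ndarray) -> tuple[float, float, float]:
    idx = np.argwhere(mask)
    return tuple(float(v) for v in idx.mean(axis=0))


def _equivalent_radius_mm(mask: np.ndarray, grid: VoxelGrid) -> float:
    return float((3 * mask.sum() * grid.voxel_volume_mm3 / (4 * math.pi)) ** (1 / 3))


def default_artifact_params(phantom: PhantomCase, artifact: str, rng: np.random.Generator) -> dict:
    """Draw artifact severity from the default ranges, seeded."""
    if artifact == "halo":
        suppression = float(rng.uniform(*HALO_SUPPRESSION_RANGE))
        thickness = float(rng.uniform(10.0, 18.0))
        shells = []
        for organ in ("bladder", "left_kidney", "right_kidney"):
            mask = phantom.organ_masks[organ]
            r_in = _equivalent_radius_mm(mask, phantom.activity) + 0.5 * max(
                phantom.activity.spacing_mm
            )
            shells.append(
                {
                    "organ": organ,
                    "center_voxel": _mask_centroid(mask),
                    "r_inner_mm": r_in,
                    "r_outer_mm": r_in + thickness,
                    "suppression": suppression,
                }
            )
        return {"shells": shells}
    if artifact == "motion":
        dz = int(rng.integers(MOTION_AXIAL_SHIFT_RANGE[0], MOTION_AXIAL_SHIFT_RANGE[1] + 1))
        return {"shift_voxels": (0, 1, dz)}
    if artifact == "truncation":
        frac = float(rng.uniform(*TRUNCATION_FOV_FRACTION_RANGE))
        return {"fov_radius_mm": frac * body_radius_mm(phantom), "fov_fraction": frac}
    if artifact == "none":
        return {}
    raise ValueError(f"unknown artifact {artifact!r}")


def simulate_pair(
    phantom: PhantomCase,
    artifact: str = "none",
    artifact_params: Optional[dict] = None,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int = 0,
    n_angles: int = DEFAULT_N_ANGLES,
    step_mm: Optional[float] = None,
    s_floor: float = S_CORRUPT_FLOOR,
    split: Optional[str] = None,
) -> PairedCase:
    """Forward-simulate one (non-AC, CT-AC) training pair.

    The non-AC image is ``activity * S`` (S from the TRUE attenuation map)
    with scaled-Poisson noise: counts drawn as
    ``Poisson(A*S / noise_scale) * noise_scale`` (mean-preserving, variance
    controlled by one knob; ``noise_scale=0`` is noiseless).  ``clean_ref``
    divides the true S back out; ``ct_ac`` divides out a survival factor
    computed from the artifact-corrupted attenuation map (floored at
    ``s_floor`` to keep truncated regions finite), then image-space halo
    suppression is applied for halo cases.
    """
    if artifact not in ARTIFACT_LABELS:
        raise ValueError(f"artifact must be one of {ARTIFACT_LABELS}")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    if artifact_params is None:
        artifact_params = default_artifact_params(phantom, artifact, rng)

    S = survival_map(phantom.mu, n_angles=n_angles, step_mm=step_mm)
    A = phantom.activity.data.astype(np.float64)
    expected = A * S.data
    if noise_scale > 0:
        counts = rng.poisson(expected / noise_scale).astype(np.float64) * noise_scale
    else:
        counts = expected
    non_ac = counts
    clean_ref = non_ac / S.data

    params = dict(artifact_params)
    if artifact == "motion":
        mu_c = inject_motion(phantom.mu, params["shift_voxels"])
        S_corrupt = survival_map(mu_c, n_angles=n_angles, step_mm=step_mm).data
    elif artifact == "truncation":
        mu_c = inject_truncation(phantom.mu, params["fov_radius_mm"])
        S_corrupt = survival_map(mu_c, n_angles=n_angles, step_mm=step_mm).data
    else:  # none and halo use the true survival map for the division
        S_corrupt = S.data

    ct_ac = non_ac / np.maximum(S_corrupt, s_floor)
    ct_grid = phantom.activity.with_data(ct_ac.astype(np.float32))
    if artifact == "halo":
        recorded = []
        for shell in params["shells"]:
            ct_grid, info = inject_halo(
                ct_grid,
                shell["center_voxel"],
                shell["r_inner_mm"],
                shell["r_outer_mm"],
                shell["suppression"],
            )
            recorded.append({**shell, "shell_voxels": info["shell_voxels"]})
        params["shells"] = recorded

    return PairedCase(
        case_id=phantom.case_id,
        non_ac=phantom.activity.with_data(non_ac.astype(np.float32)),
        ct_ac=ct_grid,
        clean_ref=phantom.activity.with_data(clean_ref.astype(np.float32)),
        artifact_label=artifact,
        split=split,
        artifact_params=params,
        seed=seed,
    )


def simulate_dataset(
    n_train: int,
    n_test: int,
    artifact_fraction: float,
    seed: int,
    artifact_mix: Optional[dict[str, float]] = None,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    geometry_jitter: float = 0.1,
    n_angles: int = DEFAULT_N_ANGLES,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
) -> list[PairedCase]:
    """Generate a seeded cohort of paired cases.

    ``artifact_fraction`` of the *training* cases receive an artifact-corrupted
    reference (types cycled through ``artifact_mix`` proportions); test cases
    are always artifact-free so the held-out evaluation target is trustworthy.
    Fully reproducible from ``seed``.
    """
    if not 0 <= artifact_fraction <= 1:
        raise ValueError("artifact_fraction must lie in [0, 1]")
    mix = artifact_mix or {"halo": 1.0, "motion": 1.0, "truncation": 1.0}
    kinds = [k for k in ("halo", "motion", "truncation") if mix.get(k, 0) > 0]
    weights = np.array([mix[k] for k in kinds], dtype=float)
    n_artifact = int(round(artifact_fraction * n_train))
    # deterministic artifact type sequence proportional to the mix
    counts = np.floor(weights / weights.sum() * n_artifact).astype(int)
    for i in np.argsort(-(weights / weights.sum() * n_artifact - counts)):
        if counts.sum() >= n_artifact:
            break
        counts[i] += 1
    artifact_sequence = [k for k, c in zip(kinds, counts) for _ in range(c)]

    master = np.random.default_rng(seed)
    order = master.permutation(n_train)
    labels = ["none"] * n_train
    for pos, kind in zip(order, artifact_sequence):
        labels[pos] = kind

    cases = []
    for idx in range(n_train + n_test):
        split = "train" if idx < n_train else "test"
        label = labels[idx] if split == "train" else "none"
        case_seed = (seed * 1_000_003 + 7919 * idx + 1) % (2**31)
        phantom = make_phantom(
            case_seed,
            grid_shape=grid_shape,
            geometry_jitter=geometry_jitter,
            spacing_mm=spacing_mm,
            case_id=f"case_{seed}_{idx:04d}",
        )
        cases.append(
            simulate_pair(
                phantom,
                artifact=label,
                noise_scale=noise_scale,
                seed=case_seed + 1,
                n_angles=n_angles,
                split=split,
            )
        )
    return cases
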