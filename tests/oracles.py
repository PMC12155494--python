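"""Independent brute-force implementations of every metric kernel.

Deliberately written as naive per-voxel loops / explicit window gathers,
sharing no code with the package implementations, so that agreement is a
genuine two-route check.
"""

import math

import numpy as np


def oracle_basic_metrics(pred, ref, mask, floor, floor_mode="exclude"):
    """ME/MAE/RMSE over mask; RE%/ARE% over mask & ref >= floor ('exclude')
    or over all mask voxels with a clamped denominator ('clamp'), by loop."""
    n = 0
    s_diff = s_abs = s_sq = 0.0
    n_rel = 0
    s_rel = s_arel = 0.0
    nx, ny, nz = pred.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                p = float(pred[i, j, k])
                r = float(ref[i, j, k])
                d = p - r
                n += 1
                s_diff += d
                s_abs += abs(d)
                s_sq += d * d
                if floor_mode == "clamp":
                    n_rel += 1
                    s_rel += d / max(r, floor)
                    s_arel += abs(d) / max(r, floor)
                elif r >= floor:
                    n_rel += 1
                    s_rel += d / r
                    s_arel += abs(d) / r
    return {
        "me": s_diff / n,
        "mae": s_abs / n,
        "rmse": math.sqrt(s_sq / n),
        "re_pct": 100.0 * s_rel / n_rel,
        "are_pct": 100.0 * s_arel / n_rel,
        "n": n,
        "n_rel": n_rel,
    }


def oracle_mean_over_voi(volume, voi):
    total = 0.0
    n = 0
    nx, ny, nz = volume.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if voi[i, j, k]:
                    total += float(volume[i, j, k])
                    n += 1
    return total / n


def oracle_ssim_map(a, b, data_range, sigma=1.5, radius=5, k1=0.01, k2=0.03):
    """Per-voxel SSIM by explicit window gather with border-truncated,
    renormalized Gaussian weights."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    g1 = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    g1 = g1 / g1.sum()
    w3 = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    data_range = max(data_range, np.finfo(np.float64).tiny)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    nx, ny, nz = a.shape
    out = np.empty((nx, ny, nz))
    for i in range(nx):
        ilo, ihi = max(0, i - radius), min(nx, i + radius + 1)
        for j in range(ny):
            jlo, jhi = max(0, j - radius), min(ny, j + radius + 1)
            for k in range(nz):
                klo, khi = max(0, k - radius), min(nz, k + radius + 1)
                w = w3[
                    ilo - i + radius : ihi - i + radius,
                    jlo - j + radius : jhi - j + radius,
                    klo - k + radius : khi - k + radius,
                ]
                w = w / w.sum()
                wa = a[ilo:ihi, jlo:jhi, klo:khi]
                wb = b[ilo:ihi, jlo:jhi, klo:khi]
                mu_a = (w * wa).sum()
                mu_b = (w * wb).sum()
                var_a = (w * wa * wa).sum() - mu_a**2
                var_b = (w * wb * wb).sum() - mu_b**2
                cov = (w * wa * wb).sum() - mu_a * mu_b
                out[i, j, k] = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
                    (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
                )
    return out


def oracle_psnr(pred, ref, mask):
    n = 0
    s_sq = 0.0
    vals = []
    nx, ny, nz = pred.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k]:
                    d = float(pred[i, j, k]) - float(ref[i, j, k])
                    s_sq += d * d
                    vals.append(float(ref[i, j, k]))
                    n += 1
    mse = s_sq / n
    L = max(vals) - min(vals)
    if mse == 0.0 or L <= 0:
        return None
    return 10.0 * math.log10(L * L / mse)


def oracle_relative_difference(a, b, floor):
    nx, ny, nz = a.shape
    out = np.empty((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                den = max(float(b[i, j, k]), floor)
                out[i, j, k] = (float(a[i, j, k]) - float(b[i, j, k])) / den * 100.0
    return out
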