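"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (double-loop
convolution, dense-ray sampling, exhaustive gamma search) used to check
the package's accelerated paths; they never share code with them.
"""

from __future__ import annotations

import numpy as np
import pytest

from epidpredict import ImageGrid
from epidpredict.synthetic import make_truth_model


@pytest.fixture(scope="session")
def truth():
    return make_truth_model()


@pytest.fixture(scope="session")
def db(truth):
    return truth.db


@pytest.fixture(scope="session")
def grid8():
    """128 x 96 detector grid (8x panel binning, 0.3125 cm pitch)."""
    return ImageGrid.binned(8)


@pytest.fixture(scope="session")
def grid16():
    """64 x 48 detector grid for the cheapest tests."""
    return ImageGrid.binned(16)


# ---------------------------------------------------------------------------
# oracles

def brute_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N^2 K^2) zero-padded linear convolution, 'same' output."""
    ny, nx = image.shape
    ky, kx = kernel.shape
    cy, cx = ky // 2, kx // 2
    out = np.zeros_like(image, dtype=float)
    for j in range(ny):
        for i in range(nx):
            acc = 0.0
            for u in range(ky):
                for v in range(kx):
                    jj = j - (u - cy)
                    ii = i - (v - cx)
                    if 0 <= jj < ny and 0 <= ii < nx:
                        acc += image[jj, ii] * kernel[u, v]
            out[j, i] = acc
    return out


def dense_ray_integral(volume, p0, p1, steps_per_voxel: int = 50) -> float:
    """Fixed-step midpoint sampling of the radiological path."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    step = min(volume.voxel_size) / steps_per_voxel
    n = int(np.ceil(length / step))
    alphas = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + alphas[:, None] * (p1 - p0)[None, :]
    total = 0.0
    shape = volume.values.shape
    idx = np.empty((n, 3), dtype=np.int64)
    inside = np.ones(n, dtype=bool)
    for k in range(3):
        lo = volume.origin[k] - 0.5 * volume.voxel_size[k]
        ik = np.floor((pts[:, k] - lo) / volume.voxel_size[k]).astype(np.int64)
        inside &= (ik >= 0) & (ik < shape[k])
        idx[:, k] = np.clip(ik, 0, shape[k] - 1)
    reds = np.where(inside, volume.values[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
    return float(reds.sum() * length / n)


def brute_gamma(reference, evaluated, criteria, step_fraction: float = 0.01) -> np.ndarray:
    """Exhaustive per-pixel gamma search on a dense shift grid.

    Bilinear interpolation of the evaluated image at every shift within
    the search disc, step ``step_fraction * dta``; NaN below threshold.
    """
    from scipy.ndimage import map_coordinates

    ref = reference.values
    ev = evaluated.values
    norm = ref.max()
    pitch_mm = reference.grid.pitch * 10.0
    dose_denom = criteria.dose_pct / 100.0 * norm
    radius = criteria.search_radius_factor * criteria.dta_mm
    step = criteria.dta_mm * step_fraction
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    DX, DY = np.meshgrid(axis, axis)
    keep = DX**2 + DY**2 <= radius**2 + 1e-12
    dx = DX[keep]
    dy = DY[keep]
    dist2 = (dx**2 + dy**2) / criteria.dta_mm**2
    out = np.full(ref.shape, np.nan)
    for j in range(ref.shape[0]):
        for i in range(ref.shape[1]):
            if ref[j, i] < criteria.low_threshold_pct / 100.0 * norm:
                continue
            coords = np.stack([j + dy / pitch_mm, i + dx / pitch_mm])
            vals = map_coordinates(ev, coords, order=1, mode="nearest")
            g2 = ((vals - ref[j, i]) / dose_denom) ** 2 + dist2
            out[j, i] = np.sqrt(g2.min())
    return out
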