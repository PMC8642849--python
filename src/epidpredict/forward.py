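"""Fluence-to-open-portal-image forward model.

The planned fluence map (ideal step-function field edges) is convolved
with two radially symmetric kernels: a Gaussian penumbra kernel

    k1(r) = c * exp(-r^2 / (2 sigma^2))

that restores the finite penumbra (focal-spot size, collimator scatter,
rounded leaf ends), and a triple-exponential detector-scatter kernel

    k2(r) = sum_i a_i * exp(-b_i * r)

that models lateral scatter inside the detector.  The convolved fluence
is converted to grayscale by the linear detector response
f(psi) = A*psi + B, and multiplied by the horn correction map HCM(r)
which restores the off-axis "horn" profile that flood-field calibration
flattens out of raw images:

    G0 = f(psi (x) k1 (x) k2) * HCM

Discrete kernels are normalized to unit sum after sampling, so the
response line (A, B), fitted on central-axis plateau values, keeps its
absolute meaning and the kernel amplitudes set relative shape only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .grid import ImageGrid


@dataclass
class KernelParams:
    """Penumbra (c, sigma) and detector-scatter (a_i, b_i) kernel shape."""

    c: float = 0.262
    sigma: float = 1.523  # cm
    a: tuple[float, float, float] = (28.9707, 0.08528, 0.003675)
    b: tuple[float, float, float] = (22.8806, 10.27858, 0.614335)  # cm^-1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(bi <= 0 for bi in self.b):
            raise ValueError("exponential rates b_i must be positive")
        if self.c < 0 or any(ai < 0 for ai in self.a):
            raise ValueError("kernel amplitudes must be non-negative")


@dataclass
class ResponseFunction:
    """Linear fluence-to-grayscale conversion G = A*psi + B."""

    A: float
    B: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("response slope A must be positive")

    def __call__(self, psi: np.ndarray) -> np.ndarray:
        return self.A * np.asarray(psi) + self.B


@dataclass
class HornCorrectionMap:
    """Radial horn-profile factor, 1.0 on the central axis.

    Stored as a sampled profile of off-axis distance r (cm) versus
    dimensionless factor; evaluated on a 2-D grid by radial symmetry
    with linear interpolation, clamped beyond the last sample.
    """

    radii: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if self.radii.ndim != 1 or self.radii.shape != self.factors.shape:
            raise ValueError("radii and factors must be matching 1-D arrays")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if abs(self.factors[0] - 1.0) > 1e-6 or self.radii[0] > 1e-9:
            raise ValueError("horn profile must start at r=0 with factor 1")
        if np.any(self.factors <= 0):
            raise ValueError("horn factors must be strictly positive")

    def __call__(self, r: np.ndarray | float) -> np.ndarray:
        return np.interp(r, self.radii, self.factors)

    @classmethod
    def flat(cls) -> "HornCorrectionMap":
        return cls(radii=np.array([0.0, 30.0]), factors=np.array([1.0, 1.0]))


@dataclass
class PortalImage:
    """2-D detector grayscale image with grid metadata."""

    values: np.ndarray
    grid: ImageGrid
    kind: str = "open"  # "open" | "transmission"
    integrated_mu: float = 0.0
    clipped_pixels: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("image values do not match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")


# ---------------------------------------------------------------------------
# kernels

def _analytic_mass_fraction(params: KernelParams, which: str, radius: float) -> float:
    """Fraction of the continuous 2-D kernel mass inside ``radius``."""
    if which == "k1":
        return 1.0 - np.exp(-(radius**2) / (2.0 * params.sigma**2))
    total = sum(ai / bi**2 for ai, bi in zip(params.a, params.b))
    inside = sum(
        ai / bi**2 * (1.0 - np.exp(-bi * radius) * (1.0 + bi * radius))
        for ai, bi in zip(params.a, params.b)
    )
    return inside / total


def build_kernel(
    params: KernelParams,
    which: str,
    grid_pitch: float,
    support_radius: float | None = None,
) -> np.ndarray:
    """Sample a radially symmetric kernel on pixel centres, unit-sum.

    ``support_radius`` defaults to 4*sigma for k1 and 8/min(b_i) for k2,
    enough to capture >=99.9% of the analytic mass; a smaller support
    triggers a warning rather than an error.
    """
    if which not in ("k1", "k2"):
        raise ValueError("which must be 'k1' or 'k2'")
    if support_radius is None:
        support_radius = 4.0 * params.sigma if which == "k1" else 8.0 / min(params.b)
    n = max(1, int(np.ceil(support_radius / grid_pitch)))
    coords = np.arange(-n, n + 1) * grid_pitch
    X, Y = np.meshgrid(coords, coords)
    r = np.hypot(X, Y)
    if which == "k1":
        k = params.c * np.exp(-(r**2) / (2.0 * params.sigma**2))
    else:
        k = sum(ai * np.exp(-bi * r) for ai, bi in zip(params.a, params.b))
    if _analytic_mass_fraction(params, which, (n + 0.5) * grid_pitch) < 0.999:
        warnings.warn(
            f"{which} support radius {support_radius:.2f} cm captures <99.9% "
            "of the analytic kernel mass",
            stacklevel=2,
        )
    return k / k.sum()


def convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Linear convolution with zero padding, output on the input grid."""
    values = np.asarray(values, dtype=float)
    if kernel.shape[0] > 2 * values.shape[0] + 1 or kernel.shape[1] > 2 * values.shape[1] + 1:
        raise ValueError("kernel larger than padded map")
    return fftconvolve(values, kernel, mode="same")


def convolve_kernels(
    values: np.ndarray,
    params: KernelParams,
    pitch: float,
    support_k1: float | None = None,
    support_k2: float | None = None,
) -> np.ndarray:
    """psi (x) k1 (x) k2 with both kernels built at the map's pitch.

    Kernel support is capped so the sampled kernel never exceeds the
    map extent (mass beyond the panel cannot influence it anyway).
    """
    cap = (min(values.shape) - 1) // 2 * pitch
    if support_k1 is None:
        support_k1 = min(4.0 * params.sigma, cap)
    if support_k2 is None:
        support_k2 = min(8.0 / min(params.b), cap)
    k1 = build_kernel(params, "k1", pitch, support_k1)
    k2 = build_kernel(params, "k2", pitch, support_k2)
    return convolve(convolve(values, k1), k2)


def compute_open_image(
    psi,
    kernel_params: KernelParams,
    response: ResponseFunction,
    hcm: HornCorrectionMap,
    support_k1: float | None = None,
    support_k2: float | None = None,
) -> PortalImage:
    """Predicted open portal image G0 = (A*(psi(x)k1(x)k2) + B) * HCM(r).

    Negative resulting grayscale values are clipped to zero; the count
    of clipped pixels is recorded on the returned image.
    """
    grid = psi.grid
    smoothed = convolve_kernels(psi.values, kernel_params, grid.pitch, support_k1, support_k2)
    g0 = response(smoothed) * hcm(grid.r)
    clipped = int(np.count_nonzero(g0 < 0))
    if clipped:
        warnings.warn(f"clipped {clipped} negative grayscale pixels", stacklevel=2)
        g0 = np.clip(g0, 0.0, None)
    return PortalImage(values=g0, grid=grid, kind="open", clipped_pixels=clipped)
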