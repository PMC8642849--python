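"""Transmission-image prediction: assemble the full forward chain.

Per up-sampled control point the pipeline is

    fluence -> open image        (kernels, response slope, horn map)
            -> primary           (divide by GFO(fs, r))
            -> attenuated        (x exp(-a(r) t / (1 + b(r) t)))
            -> transmission      (x (1 + SPR(L, fs, t, r)))

with t and L per pixel from ray tracing at the control point's gantry
angle, and fs the equivalent square of that control point's aperture.
Control-point images are superimposed into the integrated prediction.
The detector offset B of the response line is applied once per
integrated acquisition (integrated-mode behaviour), not once per
control point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .database import ParameterDatabase
from .forward import PortalImage, ResponseFunction, convolve_kernels
from .grid import DEFAULT_SAD, ImageGrid
from .plan import Beam, TreatmentPlan, aperture_coverage, rasterize_fluence, upsample_control_points
from .raytrace import BeamGeometry, REDVolume, ThicknessMaps, thickness_maps
from .commission import equivalent_square


@dataclass
class PredictConfig:
    grid: ImageGrid
    upsample_factor: int = 5
    leaf_transmission: float = 0.0
    sad: float = DEFAULT_SAD
    angle_quantum: float = 0.5  # degrees; thickness maps cached per bin
    red_threshold: float = 0.05
    apply_offset: bool = True
    retain_per_cp: bool = False


@dataclass
class PredictionResult:
    predicted: PortalImage
    per_cp_images: list[np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)


def primary_from_open(g0: np.ndarray, fs: float, db: ParameterDatabase, grid: ImageGrid) -> np.ndarray:
    """Primary grayscale of the open image: G0 / GFO(fs, r)."""
    gfo = db.gfo(fs, grid.r)
    if np.any(gfo < 1.0 - 1e-9):
        raise ValueError("corrupt database: GFO below 1")
    return np.asarray(g0) / gfo


def attenuate_primary(g0p: np.ndarray, t_map: np.ndarray, db: ParameterDatabase, grid: ImageGrid) -> np.ndarray:
    """Primary of the transmission image: apply saturated-exponential
    attenuation through the per-pixel water-equivalent thickness."""
    g0p = np.asarray(g0p)
    t_map = np.asarray(t_map)
    if g0p.shape != t_map.shape:
        raise ValueError("grids not congruent")
    return g0p * db.attenuation.transmission(t_map, grid.r)


def add_scatter(
    gtrp: np.ndarray,
    fs: float,
    t_map: np.ndarray,
    L_map: np.ndarray,
    db: ParameterDatabase,
    grid: ImageGrid,
) -> np.ndarray:
    """Total transmission image: multiply by (1 + SPR(L, fs, t, r))."""
    if fs <= 0:
        raise ValueError("field size must be positive")
    spr = db.spr(L_map, fs, t_map, grid.r)
    if np.any(spr < -1e-9):
        raise ValueError("corrupt database: negative SPR")
    return np.asarray(gtrp) * (1.0 + spr)


def _cached_thickness(cache: dict, volume, angle: float, quantum: float, grid, sad, sdd, red_threshold) -> ThicknessMaps:
    key = round(angle / quantum) * quantum % 360.0
    if key not in cache:
        geom = BeamGeometry(gantry_angle=key, sad=sad, sdd=sdd)
        cache[key] = thickness_maps(volume, geom, grid, red_threshold)
    return cache[key]


def predict_transmission(
    plan: TreatmentPlan,
    volume: REDVolume | None,
    db: ParameterDatabase,
    config: PredictConfig,
) -> PredictionResult:
    """Integrated predicted transmission image for all beams of a plan."""
    grid = config.grid
    plan_up = upsample_control_points(plan, config.upsample_factor)
    total = np.zeros(grid.shape)
    per_cp: list[np.ndarray] | None = [] if config.retain_per_cp else None
    cache: dict = {}
    diag = {"equivalent_squares": [], "clipped_pixels": 0, "skipped_cps": 0}
    empty_maps = ThicknessMaps(
        t_map=np.zeros(grid.shape), L_map=np.full(grid.shape, grid.sdd), grid=grid
    )
    for beam in plan_up.beams:
        cps = beam.control_points
        for k in range(len(cps) - 1):
            c0, c1 = cps[k], cps[k + 1]
            psi = rasterize_fluence((c0, c1), grid, config.leaf_transmission, config.sad)
            dmu = c1.cumulative_mu_fraction - c0.cumulative_mu_fraction
            if dmu <= 0 or not np.any(psi.values):
                diag["skipped_cps"] += 1
                if per_cp is not None:
                    per_cp.append(np.zeros(grid.shape))
                continue
            psi.values *= beam.total_mu  # MU units
            fs = equivalent_square(
                psi, magnification=grid.sdd / config.sad
            )
            if fs <= 0:
                diag["skipped_cps"] += 1
                if per_cp is not None:
                    per_cp.append(np.zeros(grid.shape))
                continue
            diag["equivalent_squares"].append(fs)
            smoothed = convolve_kernels(psi.values, db.kernel, grid.pitch)
            g0 = db.response.A * smoothed * db.hcm(grid.r)  # offset applied once, later
            if volume is not None:
                angle = 0.5 * (c0.gantry_angle + c1.gantry_angle)
                maps = _cached_thickness(
                    cache, volume, angle, config.angle_quantum, grid,
                    config.sad, grid.sdd, config.red_threshold,
                )
            else:
                maps = empty_maps
            try:
                g0p = primary_from_open(g0, fs, db, grid)
                gtrp = attenuate_primary(g0p, maps.t_map, db, grid)
                gtr = add_scatter(gtrp, fs, maps.t_map, maps.L_map, db, grid)
            except ValueError as exc:
                raise ValueError(f"control point {k}: {exc}") from exc
            total += gtr
            if per_cp is not None:
                per_cp.append(gtr)
    if config.apply_offset:
        total = total + db.response.B
    clipped = int(np.count_nonzero(total < 0))
    if clipped:
        diag["clipped_pixels"] = clipped
        total = np.clip(total, 0.0, None)
    mu_total = sum(b.total_mu for b in plan.beams)
    predicted = PortalImage(
        values=total, grid=grid, kind="transmission",
        integrated_mu=mu_total, clipped_pixels=clipped,
    )
    return PredictionResult(predicted=predicted, per_cp_images=per_cp, diagnostics=diag)
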