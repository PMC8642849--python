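"""Global gamma-index comparison of portal images.

The gamma index combines a dose-difference criterion (percent of a
global normalization, here the maximum of the reference image) with a
distance-to-agreement (DTA) criterion:

    gamma(p) = min over shifts d of
               sqrt( (D_eval(p+d) - D_ref(p))^2 / (dD * D_norm)^2
                     + |d|^2 / dta^2 )

The evaluated image is bilinearly interpolated at sub-pixel shifts; the
search covers a disc of radius 3*dta sampled at dta/10 steps.
Reference pixels below the low-dose threshold are excluded (NaN in the
gamma map, never 0).  A pixel passes when gamma <= 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .forward import PortalImage


@dataclass
class GammaCriteria:
    dose_pct: float = 3.0  # % of the global normalization
    dta_mm: float = 2.0
    low_threshold_pct: float = 10.0
    search_radius_factor: float = 3.0  # search disc radius in units of dta
    step_fraction: float = 0.1  # search step in units of dta

    def __post_init__(self) -> None:
        if min(self.dose_pct, self.dta_mm, self.low_threshold_pct) <= 0:
            raise ValueError("gamma criteria must be strictly positive")


@dataclass
class GammaResult:
    gamma_map: np.ndarray  # NaN where excluded
    pass_rate: float  # % of evaluated pixels with gamma <= 1
    mean_gamma: float
    criteria: GammaCriteria
    normalization: float
    n_evaluated: int


def _shift_offsets(criteria: GammaCriteria) -> np.ndarray:
    """Search-disc shifts in mm, sorted by radius (ascending)."""
    step = criteria.dta_mm * criteria.step_fraction
    radius = criteria.dta_mm * criteria.search_radius_factor
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    DX, DY = np.meshgrid(axis, axis)
    d2 = DX**2 + DY**2
    keep = d2 <= radius**2 + 1e-12
    shifts = np.column_stack([DX[keep], DY[keep], d2[keep]])
    return shifts[np.argsort(shifts[:, 2])]


def gamma_map(
    reference: PortalImage,
    evaluated: PortalImage,
    criteria: GammaCriteria | None = None,
) -> GammaResult:
    """Global gamma analysis of an evaluated image against a reference.

    Grids must be congruent (same shape and pitch).  Shifts are sorted
    by distance so the search can stop as soon as the pure distance
    term exceeds every pixel's current best gamma.
    """
    criteria = criteria or GammaCriteria()
    if not reference.grid.congruent(evaluated.grid):
        raise ValueError("reference and evaluated grids are not congruent")
    ref = reference.values
    ev = evaluated.values
    norm = float(ref.max())
    if norm <= 0:
        raise ValueError("reference image has no positive signal")
    mask = ref >= criteria.low_threshold_pct / 100.0 * norm
    if not np.any(mask):
        raise ValueError("empty evaluation region: all pixels below threshold")

    pitch_mm = reference.grid.pitch * 10.0
    dose_denom = criteria.dose_pct / 100.0 * norm
    radius = criteria.search_radius_factor * criteria.dta_mm
    jj, ii = np.nonzero(mask)
    base = np.stack([jj.astype(float), ii.astype(float)])
    ref_vals = ref[mask]

    # coarse global pass over the whole search disc
    best = np.full(ref_vals.shape, np.inf)
    best_shift = np.zeros((2, ref_vals.size))  # (dx, dy) per pixel, mm
    for dx, dy, d2 in _shift_offsets(criteria):
        dist_term = d2 / criteria.dta_mm**2
        if dist_term >= best.max():
            break  # no remaining shift can improve any pixel
        coords = base + np.array([[dy / pitch_mm], [dx / pitch_mm]])
        vals = map_coordinates(ev, coords, order=1, mode="nearest")
        g2 = ((vals - ref_vals) / dose_denom) ** 2 + dist_term
        better = g2 < best
        best[better] = g2[better]
        best_shift[0, better] = dx
        best_shift[1, better] = dy

    # fine local pass: refine around each pixel's coarse optimum at a
    # tenth of the coarse step, over a box of +-1.5 coarse steps (all
    # pixels share the relative-offset grid, so this stays vectorized)
    coarse_step = criteria.dta_mm * criteria.step_fraction
    fine_step = coarse_step / 10.0
    n_fine = 15
    fine_axis = np.arange(-n_fine, n_fine + 1) * fine_step
    for fdy in fine_axis:
        for fdx in fine_axis:
            if fdx == 0.0 and fdy == 0.0:
                continue
            dx = best_shift[0] + fdx
            dy = best_shift[1] + fdy
            d2 = dx**2 + dy**2
            inside = d2 <= radius**2 + 1e-12
            if not np.any(inside):
                continue
            coords = base[:, inside] + np.stack([dy[inside] / pitch_mm, dx[inside] / pitch_mm])
            vals = map_coordinates(ev, coords, order=1, mode="nearest")
            g2 = ((vals - ref_vals[inside]) / dose_denom) ** 2 + d2[inside] / criteria.dta_mm**2
            sub = best[inside]
            np.minimum(sub, g2, out=sub)
            best[inside] = sub

    gamma = np.full(ref.shape, np.nan)
    gamma[mask] = np.sqrt(best)
    evaluated_vals = gamma[mask]
    pass_rate = 100.0 * float(np.count_nonzero(evaluated_vals <= 1.0)) / evaluated_vals.size
    return GammaResult(
        gamma_map=gamma,
        pass_rate=pass_rate,
        mean_gamma=float(evaluated_vals.mean()),
        criteria=criteria,
        normalization=norm,
        n_evaluated=int(evaluated_vals.size),
    )


def compare_report(result: GammaResult, out_dir: str | Path, stem: str = "gamma") -> dict:
    """Write a machine-readable summary plus histogram/overlay figures.

    Returns the summary dict; JSON is written with sorted keys so a
    re-generated report is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    finite = result.gamma_map[np.isfinite(result.gamma_map)]
    summary = {
        "criteria": {
            "dose_pct": result.criteria.dose_pct,
            "dta_mm": result.criteria.dta_mm,
            "low_threshold_pct": result.criteria.low_threshold_pct,
        },
        "normalization": "global max of reference",
        "normalization_value": result.normalization,
        "pass_rate": round(result.pass_rate, 4),
        "mean_gamma": round(result.mean_gamma, 6),
        "n_evaluated": result.n_evaluated,
        "max_gamma": round(float(finite.max()), 6),
    }
    json_path = out_dir / f"{stem}_summary.json"
    json_path.write_text(json.dumps(summary, sort_keys=True, indent=1) + "\n")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.hist(finite, bins=50, color="steelblue")
    ax1.axvline(1.0, color="crimson", ls="--")
    ax1.set_xlabel("gamma")
    ax1.set_ylabel("pixels")
    ax1.set_title(f"pass rate {result.pass_rate:.1f}%")
    im = ax2.imshow(result.gamma_map, cmap="viridis", origin="lower")
    fig.colorbar(im, ax=ax2, label="gamma")
    ax2.set_title(f"mean gamma {result.mean_gamma:.3f}")
    fig.tight_layout()
    fig.savefig(out_dir / f"{stem}_map.png", dpi=110)
    plt.close(fig)
    return summary
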