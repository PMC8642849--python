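"""Radiological path length and exit air gap through a density volume.

The patient or phantom is a 3-D grid of relative electron density
(RED, water = 1).  For each detector pixel, a ray is cast from the
gantry-rotated source to the pixel centre and the water-equivalent
thickness t (sum of intersection length times RED over traversed
voxels) and the exit air gap L (distance from the last dense voxel
along the ray to the detector plane) are computed with an exact
incremental voxel-traversal (Siddon) scheme: all parametric crossings
of the three axis-aligned plane families are merged and sorted, and
each inter-crossing segment is attributed to the voxel containing its
midpoint.

Coordinates are the fixed machine frame: x lateral, y vertical (up),
z along the couch; the isocenter is the origin.  At gantry 0 the source
sits at (0, SAD, 0) and the beam travels down -y; the gantry rotates
the source about the z axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import DEFAULT_SAD, DEFAULT_SDD, ImageGrid


@dataclass
class REDVolume:
    """Axis-aligned relative-electron-density grid.

    ``values`` has shape (nx, ny, nz); ``origin`` is the world position
    of the centre of voxel (0, 0, 0); ``voxel_size`` is the (dx, dy,
    dz) edge lengths in cm.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("RED volume must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("relative electron density must be non-negative")

    def shifted(self, delta: tuple[float, float, float]) -> "REDVolume":
        """Volume rigidly translated by ``delta`` (cm) in world space."""
        o = self.origin
        return REDVolume(
            values=self.values,
            voxel_size=self.voxel_size,
            origin=(o[0] + delta[0], o[1] + delta[1], o[2] + delta[2]),
        )

    def plane_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-boundary plane coordinates along each axis."""
        edges = []
        for k in range(3):
            n = self.values.shape[k]
            lo = self.origin[k] - 0.5 * self.voxel_size[k]
            edges.append(lo + np.arange(n + 1) * self.voxel_size[k])
        return tuple(edges)


@dataclass
class BeamGeometry:
    gantry_angle: float = 0.0  # degrees
    sad: float = DEFAULT_SAD
    sdd: float = DEFAULT_SDD
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.sad < self.sdd:
            raise ValueError("require 0 < SAD < SDD")

    def source_position(self) -> np.ndarray:
        th = math.radians(self.gantry_angle)
        iso = np.asarray(self.isocenter, dtype=float)
        return iso + self.sad * np.array([math.sin(th), math.cos(th), 0.0])

    def detector_center(self) -> np.ndarray:
        th = math.radians(self.gantry_angle)
        iso = np.asarray(self.isocenter, dtype=float)
        return iso - (self.sdd - self.sad) * np.array([math.sin(th), math.cos(th), 0.0])

    def detector_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane unit vectors (e_u for image x, e_v for image y)."""
        th = math.radians(self.gantry_angle)
        e_u = np.array([math.cos(th), -math.sin(th), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        return e_u, e_v


@dataclass
class ThicknessMaps:
    t_map: np.ndarray  # cm water-equivalent
    L_map: np.ndarray  # cm exit air gap
    grid: ImageGrid


# ---------------------------------------------------------------------------
# HU -> RED

def hu_to_red(
    ct: np.ndarray,
    calibration: np.ndarray,
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float],
) -> REDVolume:
    """Convert a HU grid to relative electron density.

    ``calibration`` is an (N, 2) array of (HU, RED) pairs, strictly
    increasing in HU and non-decreasing in RED; values are linearly
    interpolated and clamped at the table ends.
    """
    calibration = np.asarray(calibration, dtype=float)
    if calibration.ndim != 2 or calibration.shape[1] != 2:
        raise ValueError("calibration must be an (N, 2) array of (HU, RED)")
    hu, red = calibration[:, 0], calibration[:, 1]
    if np.any(np.diff(hu) <= 0) or np.any(np.diff(red) < 0):
        raise ValueError("calibration table must be monotone")
    values = np.interp(np.asarray(ct, dtype=float), hu, red)
    return REDVolume(values=values, voxel_size=voxel_size, origin=origin)


#: Conventional two-segment HU->RED curve (air, water, dense bone).
DEFAULT_HU_RED = np.array(
    [[-1000.0, 0.0], [0.0, 1.0], [1000.0, 1.55], [3000.0, 2.5]]
)


# ---------------------------------------------------------------------------
# Siddon traversal

def _segments(volume: REDVolume, p0: np.ndarray, p1: np.ndarray):
    """Sorted crossing parameters, segment REDs and the ray length.

    Returns (alphas, reds) where ``alphas`` are the sorted traversal
    parameters in [0, 1] (including endpoints) and ``reds[i]`` is the
    RED attributed to segment [alphas[i], alphas[i+1]] (0 outside the
    volume).
    """
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length <= 0:
        raise ValueError("degenerate zero-length ray")
    edges = volume.plane_edges()
    crossings = [np.array([0.0, 1.0])]
    for k in range(3):
        if abs(d[k]) > 1e-12:
            a = (edges[k] - p0[k]) / d[k]
            crossings.append(a[(a > 0.0) & (a < 1.0)])
    alphas = np.unique(np.concatenate(crossings))
    mids = p0[None, :] + np.multiply.outer(0.5 * (alphas[:-1] + alphas[1:]), d)
    idx = np.empty((mids.shape[0], 3), dtype=np.int64)
    inside = np.ones(mids.shape[0], dtype=bool)
    for k in range(3):
        lo = volume.origin[k] - 0.5 * volume.voxel_size[k]
        ik = np.floor((mids[:, k] - lo) / volume.voxel_size[k]).astype(np.int64)
        inside &= (ik >= 0) & (ik < volume.values.shape[k])
        idx[:, k] = np.clip(ik, 0, volume.values.shape[k] - 1)
    reds = np.where(inside, volume.values[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
    return alphas, reds, length


def radiological_path(volume: REDVolume, p0, p1) -> float:
    """Water-equivalent thickness along the segment p0 -> p1, in cm."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    alphas, reds, length = _segments(volume, p0, p1)
    return float(np.dot(np.diff(alphas), reds) * length)


def exit_air_gap(
    volume: REDVolume,
    p0,
    p1,
    red_threshold: float = 0.05,
    default: float | None = None,
) -> float:
    """Distance from the beam's material exit point to the ray end.

    The exit point is the far boundary of the last traversed segment
    whose RED exceeds ``red_threshold`` (default 0.05: excludes air,
    keeps lung).  If no segment exceeds the threshold the conventional
    ``default`` is returned (the SDD when called through
    :func:`thickness_maps`, else the full ray length).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    alphas, reds, length = _segments(volume, p0, p1)
    dense = np.nonzero(reds > red_threshold)[0]
    if dense.size == 0:
        return float(default) if default is not None else length
    return float((1.0 - alphas[dense[-1] + 1]) * length)


def _trace(volume: REDVolume, p0: np.ndarray, p1: np.ndarray, red_threshold: float):
    """(t, L-or-None) in one traversal; L is None for all-air rays."""
    alphas, reds, length = _segments(volume, p0, p1)
    t = float(np.dot(np.diff(alphas), reds) * length)
    dense = np.nonzero(reds > red_threshold)[0]
    if dense.size == 0:
        return t, None
    return t, float((1.0 - alphas[dense[-1] + 1]) * length)


def thickness_maps(
    volume: REDVolume,
    geom: BeamGeometry,
    grid: ImageGrid,
    red_threshold: float = 0.05,
) -> ThicknessMaps:
    """Per-pixel water-equivalent thickness and exit air gap.

    Rays run from the source to each detector pixel centre.  Pixels
    whose ray never meets material above the RED threshold get t = 0
    and L = SDD by convention.
    """
    src = geom.source_position()
    center = geom.detector_center()
    e_u, e_v = geom.detector_axes()
    # volume entirely behind the detector plane is a geometry error
    axis = (center - src) / geom.sdd
    corners = np.array(np.meshgrid(*[(e[0], e[-1]) for e in volume.plane_edges()])).reshape(3, -1).T
    if np.min((corners - src) @ axis) >= geom.sdd:
        raise ValueError("volume lies entirely behind the detector plane")
    t_map = np.zeros(grid.shape)
    L_map = np.full(grid.shape, geom.sdd)
    for j, yv in enumerate(grid.y):
        row_targets = center + np.outer(grid.x, e_u) + yv * e_v
        for i in range(grid.nx):
            t, L = _trace(volume, src, row_targets[i], red_threshold)
            t_map[j, i] = t
            if L is not None:
                L_map[j, i] = L
    return ThicknessMaps(t_map=t_map, L_map=L_map, grid=grid)
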