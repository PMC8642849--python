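"""Detector-plane grid geometry.

The amorphous-silicon panel modelled here has a 40 x 30 cm2 active area
with 1024 x 768 native pixels and sits at 150 cm source-to-detector
distance (SDD).  All images (fluence maps, open portal images,
transmission images) share one grid convention: pixel centres, origin on
the beam central axis at the grid centre, x increasing with column
index, y increasing with row index.  Off-axis distance r = sqrt(x^2+y^2)
is measured in cm in the detector plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

PANEL_WIDTH_CM = 40.0
PANEL_HEIGHT_CM = 30.0
NATIVE_COLS = 1024
NATIVE_ROWS = 768

DEFAULT_SDD = 150.0
DEFAULT_SAD = 100.0


@dataclass(frozen=True)
class ImageGrid:
    """Regular pixel grid in the detector plane.

    Parameters
    ----------
    nx, ny
        Number of columns / rows.  Arrays on this grid have shape
        ``(ny, nx)``.
    pitch
        Pixel pitch in cm at the detector plane.
    sdd
        Source-to-detector distance in cm.
    """

    nx: int
    ny: int
    pitch: float
    sdd: float = DEFAULT_SDD

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.pitch <= 0:
            raise ValueError("grid must have positive dimensions and pitch")

    @classmethod
    def binned(cls, binning: int = 2, sdd: float = DEFAULT_SDD) -> "ImageGrid":
        """Panel grid with ``binning`` x ``binning`` pixel aggregation."""
        if binning < 1 or NATIVE_COLS % binning or NATIVE_ROWS % binning:
            raise ValueError(f"binning must divide {NATIVE_COLS}x{NATIVE_ROWS}")
        return cls(
            nx=NATIVE_COLS // binning,
            ny=NATIVE_ROWS // binning,
            pitch=PANEL_WIDTH_CM / NATIVE_COLS * binning,
            sdd=sdd,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @cached_property
    def x(self) -> np.ndarray:
        """Column-centre x coordinates, cm."""
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pitch

    @cached_property
    def y(self) -> np.ndarray:
        """Row-centre y coordinates, cm."""
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pitch

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    @cached_property
    def r(self) -> np.ndarray:
        """Off-axis distance map r = sqrt(x^2 + y^2), cm, shape (ny, nx)."""
        X, Y = self.mesh()
        return np.hypot(X, Y)

    def congruent(self, other: "ImageGrid") -> bool:
        return (
            self.nx == other.nx
            and self.ny == other.ny
            and abs(self.pitch - other.pitch) < 1e-12
        )
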