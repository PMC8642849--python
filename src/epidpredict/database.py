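"""Commissioned parameter database: GFO, attenuation and SPR tables.

The forward model is driven entirely by quantities commissioned from
detector measurements:

* ``GFOTable``       — global field output factor GFO(fs, r), the ratio
  of total to primary grayscale in the open image as a function of
  equivalent-square field size fs and off-axis distance r;
* ``AttenuationTable`` — thickness-saturated exponential attenuation
  coefficients a(r), b(r) of the primary beam in water, per off-axis
  distance (beam softening makes a(r) grow off-axis);
* ``SPRTable``       — scatter-to-primary ratio SPR(L, fs, t, r) of the
  transmission image versus exit air gap L, field size fs,
  water-equivalent thickness t and off-axis distance r;

plus the penumbra/detector kernels, the linear response and the horn
correction profile.  Lookups are multilinear on the stored grids;
coordinates outside a grid are clamped to the boundary (the SPR was
measured only out to r = 10 cm, so larger radii reuse the 10 cm row).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .forward import HornCorrectionMap, KernelParams, ResponseFunction


def _clamped_interpolator(axes: tuple[np.ndarray, ...], values: np.ndarray):
    rgi = RegularGridInterpolator(axes, values, method="linear", bounds_error=False)

    def interp(*coords):
        pts = np.broadcast_arrays(*coords)
        shape = pts[0].shape
        stacked = np.stack(
            [np.clip(np.ravel(p).astype(float), ax[0], ax[-1]) for p, ax in zip(pts, axes)],
            axis=-1,
        )
        if np.any(np.isnan(stacked)):
            raise ValueError("NaN coordinate in table lookup")
        return rgi(stacked).reshape(shape)

    return interp


def _monotone_violations(values, axis, axis_name, increasing, tol=1e-9):
    d = np.diff(values, axis=axis)
    bad = d < -tol if increasing else d > tol
    n = int(np.count_nonzero(bad))
    if n:
        word = "non-decreasing" if increasing else "non-increasing"
        return [f"{axis_name}: {n} samples violate {word} ordering"]
    return []


@dataclass
class GFOTable:
    fs: np.ndarray  # cm, equivalent square, increasing
    r: np.ndarray  # cm, off-axis distance, increasing
    values: np.ndarray  # (len(fs), len(r))

    def __post_init__(self) -> None:
        self.fs = np.asarray(self.fs, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.fs.size, self.r.size):
            raise ValueError("GFO table shape mismatch")
        self._interp = _clamped_interpolator((self.fs, self.r), self.values)

    def __call__(self, fs, r):
        return self._interp(fs, r)

    def violations(self) -> list[str]:
        out = []
        if np.any(self.values < 1.0 - 1e-9):
            out.append("GFO below 1 encountered")
        out += _monotone_violations(self.values, 0, "GFO vs fs", increasing=True)
        out += _monotone_violations(self.values, 1, "GFO vs r", increasing=False)
        return out


@dataclass
class AttenuationTable:
    r: np.ndarray  # cm
    a: np.ndarray  # cm^-1
    b: np.ndarray  # cm^-1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (self.r.shape == self.a.shape == self.b.shape):
            raise ValueError("attenuation table shape mismatch")
        if np.any(self.a <= 0) or np.any(self.b < 0):
            raise ValueError("attenuation coefficients out of range")

    def coefficients(self, r):
        """Linearly interpolated (a(r), b(r)), clamped at the table ends."""
        return np.interp(r, self.r, self.a), np.interp(r, self.r, self.b)

    def transmission(self, t, r):
        """Primary transmission T = exp(-a(r)*t / (1 + b(r)*t))."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative thickness")
        a, b = self.coefficients(r)
        return np.exp(-a * t / (1.0 + b * t))

    def violations(self) -> list[str]:
        return _monotone_violations(self.a, 0, "a vs r", increasing=True)


@dataclass
class SPRTable:
    L: np.ndarray  # cm air gap
    fs: np.ndarray  # cm field size
    t: np.ndarray  # cm water-equivalent thickness
    r: np.ndarray  # cm off-axis distance
    values: np.ndarray  # (len(L), len(fs), len(t), len(r))

    def __post_init__(self) -> None:
        for name in ("L", "fs", "t", "r"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.L.size, self.fs.size, self.t.size, self.r.size)
        if self.values.shape != expected:
            raise ValueError(f"SPR table shape {self.values.shape} != {expected}")
        self._interp = _clamped_interpolator((self.L, self.fs, self.t, self.r), self.values)

    def __call__(self, L, fs, t, r):
        return self._interp(L, fs, t, r)

    def violations(self) -> list[str]:
        out = []
        if np.any(self.values < -1e-9):
            out.append("negative SPR encountered")
        out += _monotone_violations(self.values, 0, "SPR vs L", increasing=False)
        out += _monotone_violations(self.values, 1, "SPR vs fs", increasing=True)
        out += _monotone_violations(self.values, 2, "SPR vs t", increasing=True)
        out += _monotone_violations(self.values, 3, "SPR vs r", increasing=False)
        return out


@dataclass
class ParameterDatabase:
    """Everything the forward model needs, commissioned or synthetic."""

    kernel: KernelParams
    response: ResponseFunction
    hcm: HornCorrectionMap
    gfo: GFOTable
    attenuation: AttenuationTable
    spr: SPRTable
    metadata: dict = field(default_factory=dict)

    def validate(self, strict: bool = False) -> list[str]:
        """Collect invariant violations across all tables.

        With ``strict`` a non-empty report raises; otherwise it is
        returned (commissioned data is never silently altered).
        """
        report = self.gfo.violations() + self.attenuation.violations() + self.spr.violations()
        # open-beam consistency: at t=0 and the largest measured air gap
        # the transmission-image scatter reduces to the open-image
        # scatter, i.e. 1 + SPR(t=0) ~= GFO.
        spr0 = self.spr(self.spr.L[-1], self.gfo.fs, 0.0, 0.0)
        gfo0 = self.gfo(self.gfo.fs, 0.0)
        if np.max(np.abs((1.0 + spr0) - gfo0)) > 0.05:
            report.append("SPR(t=0) inconsistent with GFO-1 beyond 0.05")
        if strict and report:
            raise ValueError("; ".join(report))
        return report


def lookup(db: ParameterDatabase, quantity: str, coords: dict):
    """Uniform lookup front-end over the database tables.

    ``coords`` uses the axis names ``fs``, ``t``, ``r``, ``L`` as
    applicable.  Multilinear interpolation on the stored grid; out-of-
    grid coordinates are clamped to the boundary.
    """
    if quantity == "gfo":
        return db.gfo(coords["fs"], coords["r"])
    if quantity == "attenuation":
        return db.attenuation.coefficients(coords["r"])
    if quantity == "spr":
        return db.spr(coords["L"], coords["fs"], coords["t"], coords["r"])
    raise ValueError(f"unknown quantity {quantity!r}")


# ---------------------------------------------------------------------------
# serialization (single JSON document; arrays as nested lists)

def save_database(db: ParameterDatabase, path: str | Path) -> None:
    doc = {
        "format": "epidpredict-db-1",
        "kernel_params": {
            "c": db.kernel.c,
            "sigma": db.kernel.sigma,
            "a": list(db.kernel.a),
            "b": list(db.kernel.b),
        },
        "response": {"A": db.response.A, "B": db.response.B},
        "hcm_profile": {
            "radii": db.hcm.radii.tolist(),
            "factors": db.hcm.factors.tolist(),
        },
        "gfo": {
            "fs": db.gfo.fs.tolist(),
            "r": db.gfo.r.tolist(),
            "values": db.gfo.values.tolist(),
        },
        "attenuation": {
            "r": db.attenuation.r.tolist(),
            "a": db.attenuation.a.tolist(),
            "b": db.attenuation.b.tolist(),
        },
        "spr": {
            "L": db.spr.L.tolist(),
            "fs": db.spr.fs.tolist(),
            "t": db.spr.t.tolist(),
            "r": db.spr.r.tolist(),
            "values": db.spr.values.tolist(),
        },
        "metadata": db.metadata,
    }
    Path(path).write_text(json.dumps(doc))


def load_database(path: str | Path) -> ParameterDatabase:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "epidpredict-db-1":
        raise ValueError(f"{path}: not an epidpredict parameter database")
    kp = doc["kernel_params"]
    return ParameterDatabase(
        kernel=KernelParams(c=kp["c"], sigma=kp["sigma"], a=tuple(kp["a"]), b=tuple(kp["b"])),
        response=ResponseFunction(A=doc["response"]["A"], B=doc["response"]["B"]),
        hcm=HornCorrectionMap(
            radii=np.array(doc["hcm_profile"]["radii"]),
            factors=np.array(doc["hcm_profile"]["factors"]),
        ),
        gfo=GFOTable(
            fs=np.array(doc["gfo"]["fs"]),
            r=np.array(doc["gfo"]["r"]),
            values=np.array(doc["gfo"]["values"]),
        ),
        attenuation=AttenuationTable(
            r=np.array(doc["attenuation"]["r"]),
            a=np.array(doc["attenuation"]["a"]),
            b=np.array(doc["attenuation"]["b"]),
        ),
        spr=SPRTable(
            L=np.array(doc["spr"]["L"]),
            fs=np.array(doc["spr"]["fs"]),
            t=np.array(doc["spr"]["t"]),
            r=np.array(doc["spr"]["r"]),
            values=np.array(doc["spr"]["values"]),
        ),
        metadata=doc.get("metadata", {}),
    )
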