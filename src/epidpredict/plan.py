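"""Treatment plans, control-point up-sampling, and fluence rasterization.

A plan is a list of beams; each beam carries a monitor-unit (MU) total
and a sequence of control points.  A control point snapshots the machine
state: gantry angle (IEC 61217), cumulative MU fraction, the 120 leaf
positions of a Millennium-120 style MLC (two banks of 60 leaves), and
the four jaw positions.  Leaf and jaw positions are stored in cm at the
isocenter plane; bank B is the negative-x bank so ``bank_b <= bank_a``
for every pair of an open aperture.

The rasterizer turns a pair of consecutive control points into a planned
fluence map on the detector grid: a binary aperture with area-weighted
edge pixels, magnified from the isocenter plane to the detector plane by
SDD/SAD, and scaled by the MU fraction delivered in the interval.  No
penumbra is modelled at this stage — field edges are ideal step
functions, and all source-size / rounded-leaf-end blur is absorbed
downstream by the penumbra kernel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .grid import DEFAULT_SAD, ImageGrid

N_LEAF_PAIRS = 60

#: Millennium-120 leaf widths at the isocenter plane, cm: 10 outer 1.0 cm
#: pairs, 40 central 0.5 cm pairs, 10 outer 1.0 cm pairs (40 cm total).
LEAF_WIDTHS_CM = np.array([1.0] * 10 + [0.5] * 40 + [1.0] * 10)
#: Leaf-pair band edges in y, cm at isocenter, ascending from -20 to +20.
LEAF_EDGES_CM = np.concatenate([[-20.0], np.cumsum(LEAF_WIDTHS_CM) - 20.0])


class PlanParseError(ValueError):
    """The plan file could not be interpreted in the requested dialect."""


class PlanValidationError(ValueError):
    """The plan violates a control-point invariant."""


@dataclass
class ControlPoint:
    index: int
    gantry_angle: float  # degrees, IEC 61217, [0, 360)
    cumulative_mu_fraction: float  # in [0, 1]
    bank_a_positions: np.ndarray  # (60,) cm at isocenter, +x bank
    bank_b_positions: np.ndarray  # (60,) cm at isocenter, -x bank
    jaw_x1: float
    jaw_x2: float
    jaw_y1: float
    jaw_y2: float

    def __post_init__(self) -> None:
        self.bank_a_positions = np.asarray(self.bank_a_positions, dtype=float)
        self.bank_b_positions = np.asarray(self.bank_b_positions, dtype=float)
        if self.bank_a_positions.shape != (N_LEAF_PAIRS,):
            raise PlanValidationError(
                f"bank A must have {N_LEAF_PAIRS} leaves, got "
                f"{self.bank_a_positions.shape}"
            )
        if self.bank_b_positions.shape != (N_LEAF_PAIRS,):
            raise PlanValidationError(
                f"bank B must have {N_LEAF_PAIRS} leaves, got "
                f"{self.bank_b_positions.shape}"
            )

    @property
    def jaws(self) -> tuple[float, float, float, float]:
        return (self.jaw_x1, self.jaw_x2, self.jaw_y1, self.jaw_y2)


@dataclass
class Beam:
    total_mu: float
    control_points: list[ControlPoint]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    technique: str = "imrt"  # "imrt" | "vmat"
    name: str = ""


@dataclass
class TreatmentPlan:
    beams: list[Beam]
    label: str = ""


@dataclass
class FluenceMap:
    """Planned fluence on the detector grid.

    ``values`` is the MU-weighted relative aperture intensity: an open
    pixel of a control-point interval delivering the full beam carries
    the interval's MU fraction.  Multiply by the beam MU total to obtain
    fluence in MU units.
    """

    values: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("fluence values do not match grid shape")


# ---------------------------------------------------------------------------
# validation

def validate_plan(plan: TreatmentPlan) -> None:
    """Raise :class:`PlanValidationError` on any invariant breach."""
    if not plan.beams:
        raise PlanValidationError("plan has no beams")
    for bi, beam in enumerate(plan.beams):
        if beam.total_mu <= 0:
            raise PlanValidationError(f"beam {bi}: total MU must be positive")
        cps = beam.control_points
        if len(cps) < 2:
            raise PlanValidationError(f"beam {bi}: needs at least 2 control points")
        fracs = [cp.cumulative_mu_fraction for cp in cps]
        if abs(fracs[0]) > 1e-9 or abs(fracs[-1] - 1.0) > 1e-9:
            raise PlanValidationError(
                f"beam {bi}: cumulative MU fractions must run from 0 to 1"
            )
        if any(b > a + 1e-9 for a, b in zip(fracs[1:], fracs[:-1])):
            raise PlanValidationError(
                f"beam {bi}: cumulative MU fractions must be non-decreasing"
            )
        for cp in cps:
            if np.any(cp.bank_b_positions > cp.bank_a_positions + 1e-9):
                raise PlanValidationError(
                    f"beam {bi} cp {cp.index}: bank B crosses bank A"
                )
            if cp.jaw_x1 > cp.jaw_x2 or cp.jaw_y1 > cp.jaw_y2:
                raise PlanValidationError(f"beam {bi} cp {cp.index}: inverted jaws")


# ---------------------------------------------------------------------------
# I/O

def _cp_from_dict(i: int, d: dict) -> ControlPoint:
    jaws = d["jaws"]
    return ControlPoint(
        index=i,
        gantry_angle=float(d["gantry"]) % 360.0,
        cumulative_mu_fraction=float(d["mu_fraction"]),
        bank_a_positions=np.asarray(d["bank_a"], dtype=float),
        bank_b_positions=np.asarray(d["bank_b"], dtype=float),
        jaw_x1=float(jaws["x1"]),
        jaw_x2=float(jaws["x2"]),
        jaw_y1=float(jaws["y1"]),
        jaw_y2=float(jaws["y2"]),
    )


def _load_json_plan(path: Path) -> TreatmentPlan:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PlanParseError(f"{path}: invalid JSON: {exc}") from exc
    if "beams" not in doc:
        raise PlanParseError(f"{path}: missing 'beams' key")
    beams = []
    for bd in doc["beams"]:
        try:
            cps = [_cp_from_dict(i, cd) for i, cd in enumerate(bd["control_points"])]
        except KeyError as exc:
            raise PlanParseError(f"{path}: control point missing field {exc}") from exc
        beams.append(
            Beam(
                total_mu=float(bd["total_mu"]),
                control_points=cps,
                isocenter=tuple(bd.get("isocenter", (0.0, 0.0, 0.0))),
                technique=bd.get("technique", "imrt"),
                name=bd.get("name", ""),
            )
        )
    return TreatmentPlan(beams=beams, label=doc.get("label", ""))


def _load_dicom_plan(path: Path, default_mu: float = 100.0) -> TreatmentPlan:
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    if not hasattr(ds, "BeamSequence"):
        raise PlanParseError(f"{path}: no BeamSequence in dataset")

    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams = []
    for b in ds.BeamSequence:
        cps_raw = getattr(b, "ControlPointSequence", None)
        if not cps_raw:
            raise PlanParseError(f"{path}: beam has no ControlPointSequence")
        final_w = float(getattr(b, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        gantry = 0.0
        bank_a = np.zeros(N_LEAF_PAIRS)
        bank_b = np.zeros(N_LEAF_PAIRS)
        jx1 = jx2 = jy1 = jy2 = 0.0
        saw_mlc = False
        cps = []
        for i, cp in enumerate(cps_raw):
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle)
            for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = dev.RTBeamLimitingDeviceType
                pos = np.asarray(dev.LeafJawPositions, dtype=float) / 10.0  # mm->cm
                if kind in ("X", "ASYMX"):
                    jx1, jx2 = pos[0], pos[1]
                elif kind in ("Y", "ASYMY"):
                    jy1, jy2 = pos[0], pos[1]
                elif kind in ("MLCX", "MLCX1", "MLCX2"):
                    if pos.size != 2 * N_LEAF_PAIRS:
                        raise PlanParseError(
                            f"{path}: MLCX has {pos.size} positions, "
                            f"expected {2 * N_LEAF_PAIRS}"
                        )
                    # DICOM order: bank 1 (negative-x side, our bank B)
                    # then bank 2 (positive-x side, our bank A).
                    bank_b = pos[:N_LEAF_PAIRS].copy()
                    bank_a = pos[N_LEAF_PAIRS:].copy()
                    saw_mlc = True
            cps.append(
                ControlPoint(
                    index=i,
                    gantry_angle=gantry % 360.0,
                    cumulative_mu_fraction=float(cp.CumulativeMetersetWeight) / final_w,
                    bank_a_positions=bank_a.copy(),
                    bank_b_positions=bank_b.copy(),
                    jaw_x1=jx1,
                    jaw_x2=jx2,
                    jaw_y1=jy1,
                    jaw_y2=jy2,
                )
            )
        if not saw_mlc:
            raise PlanParseError(f"{path}: beam has no MLCX leaf position sequence")
        iso = (0.0, 0.0, 0.0)
        if hasattr(cps_raw[0], "IsocenterPosition"):
            iso = tuple(float(v) / 10.0 for v in cps_raw[0].IsocenterPosition)
        beams.append(
            Beam(
                total_mu=metersets.get(int(b.BeamNumber), default_mu),
                control_points=cps,
                isocenter=iso,
                technique="vmat" if len({c.gantry_angle for c in cps}) > 1 else "imrt",
                name=str(getattr(b, "BeamName", "")),
            )
        )
    return TreatmentPlan(beams=beams, label=str(getattr(ds, "RTPlanLabel", "")))


def load_plan(path: str | Path, dialect: str = "json") -> TreatmentPlan:
    """Load a treatment plan from a JSON fixture or a DICOM-RT Plan file.

    The loaded plan is validated against the control-point invariants
    (monotone cumulative MU fractions running 0 -> 1, no bank crossing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "json":
        plan = _load_json_plan(path)
    elif dialect == "dicom":
        plan = _load_dicom_plan(path)
    else:
        raise ValueError(f"unknown plan dialect {dialect!r}")
    validate_plan(plan)
    return plan


def write_plan(plan: TreatmentPlan, path: str | Path) -> None:
    """Serialize a plan to the JSON fixture dialect."""
    doc = {
        "label": plan.label,
        "beams": [
            {
                "total_mu": beam.total_mu,
                "isocenter": list(beam.isocenter),
                "technique": beam.technique,
                "name": beam.name,
                "control_points": [
                    {
                        "gantry": cp.gantry_angle,
                        "mu_fraction": cp.cumulative_mu_fraction,
                        "bank_a": cp.bank_a_positions.tolist(),
                        "bank_b": cp.bank_b_positions.tolist(),
                        "jaws": {
                            "x1": cp.jaw_x1,
                            "x2": cp.jaw_x2,
                            "y1": cp.jaw_y1,
                            "y2": cp.jaw_y2,
                        },
                    }
                    for cp in beam.control_points
                ],
            }
            for beam in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# up-sampling

def _interp_angle(g0: float, g1: float, f: float) -> float:
    """Linear gantry interpolation along the shortest arc across 0/360."""
    delta = (g1 - g0 + 180.0) % 360.0 - 180.0
    return (g0 + f * delta) % 360.0


def upsample_control_points(plan: TreatmentPlan, factor: int = 5) -> TreatmentPlan:
    """Subdivide every control-point interval into ``factor`` sub-intervals.

    Leaf positions, jaws and cumulative MU fraction are linearly
    interpolated; the gantry angle is interpolated along the shortest
    arc so VMAT arcs crossing 360/0 behave.  A beam with N control
    points becomes one with ``factor*(N-1)+1``.
    """
    if factor < 1:
        raise ValueError("up-sampling factor must be >= 1")
    if factor == 1:
        return plan
    new_beams = []
    for beam in plan.beams:
        cps = beam.control_points
        out: list[ControlPoint] = []
        for k in range(len(cps) - 1):
            c0, c1 = cps[k], cps[k + 1]
            for s in range(factor):
                f = s / factor
                out.append(
                    ControlPoint(
                        index=len(out),
                        gantry_angle=_interp_angle(c0.gantry_angle, c1.gantry_angle, f),
                        cumulative_mu_fraction=(1 - f) * c0.cumulative_mu_fraction
                        + f * c1.cumulative_mu_fraction,
                        bank_a_positions=(1 - f) * c0.bank_a_positions
                        + f * c1.bank_a_positions,
                        bank_b_positions=(1 - f) * c0.bank_b_positions
                        + f * c1.bank_b_positions,
                        jaw_x1=(1 - f) * c0.jaw_x1 + f * c1.jaw_x1,
                        jaw_x2=(1 - f) * c0.jaw_x2 + f * c1.jaw_x2,
                        jaw_y1=(1 - f) * c0.jaw_y1 + f * c1.jaw_y1,
                        jaw_y2=(1 - f) * c0.jaw_y2 + f * c1.jaw_y2,
                    )
                )
        last = cps[-1]
        out.append(replace(last, index=len(out)))
        new_beams.append(
            Beam(
                total_mu=beam.total_mu,
                control_points=out,
                isocenter=beam.isocenter,
                technique=beam.technique,
                name=beam.name,
            )
        )
    return TreatmentPlan(beams=new_beams, label=plan.label)


# ---------------------------------------------------------------------------
# rasterization

def _interval_coverage(lo: float, hi: float, centers: np.ndarray, pitch: float) -> np.ndarray:
    """Fraction of each pixel extent covered by the interval [lo, hi]."""
    left = centers - pitch / 2.0
    right = centers + pitch / 2.0
    return np.clip((np.minimum(hi, right) - np.maximum(lo, left)) / pitch, 0.0, 1.0)


def aperture_coverage(cp: ControlPoint, grid: ImageGrid, sad: float = DEFAULT_SAD) -> np.ndarray:
    """Per-pixel open-area fraction of a control point's MLC+jaw aperture.

    Positions are projected from the isocenter plane to the detector
    plane by the magnification SDD/SAD (1.5 for the standard geometry).
    Pixels fully inside the aperture get 1, pixels straddling a leaf or
    jaw edge get the exact covered-area fraction (the aperture is a
    union of axis-aligned rectangles, so coverage factorizes into x and
    y overlaps).
    """
    mag = grid.sdd / sad
    cov = np.zeros(grid.shape)
    jx1, jx2 = cp.jaw_x1 * mag, cp.jaw_x2 * mag
    jy1, jy2 = cp.jaw_y1 * mag, cp.jaw_y2 * mag
    for p in range(N_LEAF_PAIRS):
        xlo = max(cp.bank_b_positions[p] * mag, jx1)
        xhi = min(cp.bank_a_positions[p] * mag, jx2)
        if xhi <= xlo:
            continue
        ylo = max(LEAF_EDGES_CM[p] * mag, jy1)
        yhi = min(LEAF_EDGES_CM[p + 1] * mag, jy2)
        if yhi <= ylo:
            continue
        cx = _interval_coverage(xlo, xhi, grid.x, grid.pitch)
        cy = _interval_coverage(ylo, yhi, grid.y, grid.pitch)
        cov += np.outer(cy, cx)
    return np.clip(cov, 0.0, 1.0)


def rasterize_fluence(
    cp_pair: tuple[ControlPoint, ControlPoint],
    grid: ImageGrid,
    leaf_transmission: float = 0.0,
    sad: float = DEFAULT_SAD,
) -> FluenceMap:
    """Rasterize one control-point interval into a planned fluence map.

    The aperture is averaged over the interval (mean of the two
    endpoint apertures) and scaled by the MU fraction delivered in the
    interval.  An optional uniform ``leaf_transmission`` fraction is
    added under closed leaves inside the jaw rectangle.
    """
    c0, c1 = cp_pair
    dmu = c1.cumulative_mu_fraction - c0.cumulative_mu_fraction
    if dmu < -1e-9:
        raise PlanValidationError("negative MU fraction in control-point interval")
    ap = 0.5 * (aperture_coverage(c0, grid, sad) + aperture_coverage(c1, grid, sad))
    if leaf_transmission > 0.0:
        mag = grid.sdd / sad
        jaw = np.outer(
            _interval_coverage(0.5 * (c0.jaw_y1 + c1.jaw_y1) * mag,
                               0.5 * (c0.jaw_y2 + c1.jaw_y2) * mag,
                               grid.y, grid.pitch),
            _interval_coverage(0.5 * (c0.jaw_x1 + c1.jaw_x1) * mag,
                               0.5 * (c0.jaw_x2 + c1.jaw_x2) * mag,
                               grid.x, grid.pitch),
        )
        ap = ap + leaf_transmission * np.clip(jaw - ap, 0.0, 1.0)
    values = dmu * ap
    if dmu > 0 and not np.any(values):
        warnings.warn("aperture entirely outside the detector grid", stacklevel=2)
    return FluenceMap(values=values, grid=grid)


def beam_fluence(
    beam: Beam,
    grid: ImageGrid,
    leaf_transmission: float = 0.0,
    sad: float = DEFAULT_SAD,
) -> FluenceMap:
    """Sum of per-interval fluence maps over a whole beam."""
    total = np.zeros(grid.shape)
    cps = beam.control_points
    for k in range(len(cps) - 1):
        total += rasterize_fluence((cps[k], cps[k + 1]), grid, leaf_transmission, sad).values
    return FluenceMap(values=total, grid=grid)
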