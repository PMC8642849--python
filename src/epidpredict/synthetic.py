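"""Synthetic ground truth: phantoms, plans, measurements, error injection.

This module stands in for the Linac + detector: it defines a complete
truth parameter database with smooth analytic tables, generates the
commissioning measurement grid (square fields of 3-20 cm, solid-water
thicknesses of 0-40 cm, off-axis distances of 0-10 cm, air gaps of
20-50 cm), simulates "measured" transmission images by running the
forward model under the truth database with optional plan/setup
perturbations and noise, and provides slab and stylized-thorax
phantoms.

Truth-table design (constants are this package's choices, documented in
docs/methods.md):

* GFO(fs, r)  = 1 + (g1*fs + g2*fs^2) * exp(-r / r_g): head+detector
  scatter grows with field size and falls off-axis; the polynomial-in-
  fs form keeps the zero-field limit exactly recoverable by quadratic
  extrapolation.
* a(r), b(r)  = measured-beam-quality attenuation rows, linearly
  interpolated between 1 cm off-axis bins, softening off-axis.
* SPR(L, fs, t, r) = (GFO(fs, r) - 1) * (1 + kt * t) * (L0 / L):
  scatter grows with field size and thickness, falls with off-axis
  distance and air gap, and reduces to the open-beam scatter GFO - 1
  at t = 0 and the reference air gap L0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .commission import MeasurementRecord, MeasurementSet, equivalent_square
from .database import AttenuationTable, GFOTable, ParameterDatabase, SPRTable
from .forward import (
    HornCorrectionMap,
    KernelParams,
    PortalImage,
    ResponseFunction,
    compute_open_image,
)
from .grid import ImageGrid
from .plan import (
    Beam,
    ControlPoint,
    FluenceMap,
    LEAF_EDGES_CM,
    N_LEAF_PAIRS,
    TreatmentPlan,
    beam_fluence,
    validate_plan,
)
from .predict import PredictConfig, predict_transmission
from .raytrace import REDVolume

# ---------------------------------------------------------------------------
# measurement grid (commissioning conditions)

FS_GRID = np.array([3.0, 4.0, 5.0, 8.0, 10.0, 12.0, 15.0, 18.0, 20.0])
T_GRID = np.array([0.0, 3.0, 5.0, 8.0, 10.0, 12.0, 15.0, 18.0, 20.0, 25.0, 30.0, 35.0, 40.0])
R_GRID = np.arange(0.0, 11.0)
L_GRID = np.array([20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0])

#: attenuation coefficient rows per off-axis cm (beam softening off-axis)
TRUTH_ATTEN_A = np.array(
    [0.0575, 0.0596, 0.0598, 0.0600, 0.0601, 0.0606, 0.0614, 0.0617, 0.0628, 0.0635, 0.0640]
)
TRUTH_ATTEN_B = np.array(
    [0.003642, 0.005063, 0.005039, 0.004948, 0.005014, 0.005135, 0.00536, 0.005288, 0.005645, 0.005791, 0.005898]
)

# truth-table shape constants
_G1, _G2 = 0.004, 1.0e-4  # GFO growth with field size
_RG = 30.0  # cm, off-axis decay length of head/detector scatter
_KT = 0.05  # per cm, SPR growth with thickness
_L0 = 50.0  # cm, reference air gap
_HORN = 3.0e-4  # per cm^2, quadratic horn amplitude


def truth_gfo_value(fs, r):
    return 1.0 + (_G1 * np.asarray(fs) + _G2 * np.asarray(fs) ** 2) * np.exp(
        -np.asarray(r) / _RG
    )


def truth_spr_value(L, fs, t, r):
    return (truth_gfo_value(fs, r) - 1.0) * (1.0 + _KT * np.asarray(t)) * (_L0 / np.asarray(L))


def truth_transmission(t, r):
    a = np.interp(r, R_GRID, TRUTH_ATTEN_A)
    b = np.interp(r, R_GRID, TRUTH_ATTEN_B)
    return np.exp(-a * np.asarray(t) / (1.0 + b * np.asarray(t)))


@dataclass
class TruthModel:
    """A complete parameter database designated as ground truth."""

    db: ParameterDatabase
    noise_sigma_pct: float = 0.5  # Gaussian grayscale sigma, % of signal
    seed: int = 0


def make_truth_model(seed: int = 0, noise_sigma_pct: float = 0.5) -> TruthModel:
    """Assemble the default synthetic truth database."""
    FS, R = np.meshgrid(FS_GRID, R_GRID, indexing="ij")
    gfo = GFOTable(fs=FS_GRID, r=R_GRID, values=truth_gfo_value(FS, R))
    L, FS4, T4, R4 = np.meshgrid(L_GRID, FS_GRID, T_GRID, R_GRID, indexing="ij")
    spr = SPRTable(
        L=L_GRID, fs=FS_GRID, t=T_GRID, r=R_GRID,
        values=truth_spr_value(L, FS4, T4, R4),
    )
    horn_r = np.arange(0.0, 25.1, 0.5)
    db = ParameterDatabase(
        kernel=KernelParams(),  # measured-beam kernel shape defaults
        response=ResponseFunction(A=2.67e5, B=-168.0),
        hcm=HornCorrectionMap(radii=horn_r, factors=1.0 + _HORN * horn_r**2),
        gfo=gfo,
        attenuation=AttenuationTable(r=R_GRID, a=TRUTH_ATTEN_A, b=TRUTH_ATTEN_B),
        spr=spr,
        metadata={"source": "synthetic truth model", "seed": seed},
    )
    return TruthModel(db=db, noise_sigma_pct=noise_sigma_pct, seed=seed)


# ---------------------------------------------------------------------------
# phantoms

def make_slab_phantom(
    thickness: float,
    lateral: float = 40.0,
    red: float = 1.0,
    voxel: float = 0.5,
) -> REDVolume:
    """Homogeneous solid-water-like slab centred at the isocenter.

    The slab is normal to the vertical (beam) axis at gantry 0 and
    spans ``lateral`` cm in x and z.  One voxel of air pads every face.
    """
    if thickness <= 0:
        raise ValueError("slab thickness must be positive")
    nxz = int(np.ceil(lateral / voxel))
    ny = int(np.ceil(thickness / voxel))
    values = np.zeros((nxz + 2, ny + 2, nxz + 2))
    values[1:-1, 1:-1, 1:-1] = red
    # scale interior voxel size so the slab thickness is exact
    dy = thickness / ny
    dxz = lateral / nxz
    origin = (
        -(nxz + 1) / 2.0 * dxz,
        -(ny + 1) / 2.0 * dy,
        -(nxz + 1) / 2.0 * dxz,
    )
    return REDVolume(values=values, voxel_size=(dxz, dy, dxz), origin=origin)


# stylized thorax geometry (cm): all chords are hand-computable.  The
# lungs sit lateral to the central mediastinal channel so the water-
# equivalent thickness of a central anterior field varies smoothly with
# position, as it does in the physical thorax phantom this stands in
# for (a property the setup-shift sensitivity analysis relies on).
THORAX_BODY_SEMI = (15.0, 10.0)  # ellipse semi-axes in (x, y)
THORAX_HALF_LENGTH = 14.0  # half-extent in z
THORAX_LUNG_CENTERS = ((-9.5, 1.0, 0.0), (9.5, 1.0, 0.0))
THORAX_LUNG_SEMI = (4.0, 6.0, 10.0)
THORAX_LUNG_RED = 0.2


def make_thorax_phantom(voxel: float = 0.5) -> REDVolume:
    """Stylized thorax: elliptical body with two low-density lungs.

    Body: ellipse with semi-axes (15, 10) cm in the axial (x, y) plane,
    28 cm long in z, RED 1.0.  Lungs: two ellipsoids of RED 0.2 with
    semi-axes (4, 6, 10) cm centred at (+-9.5, 1, 0).  The wide gap
    between the lungs acts as a mediastinum of unit density, so a
    central anterior field sees a smoothly varying thickness.  All
    expected chord lengths follow from the analytic geometry.
    """
    ax, ay = THORAX_BODY_SEMI
    nx = int(np.ceil(2 * (ax + 1) / voxel))
    ny = int(np.ceil(2 * (ay + 1) / voxel))
    nz = int(np.ceil(2 * (THORAX_HALF_LENGTH + 1) / voxel))
    origin = (-(nx - 1) / 2.0 * voxel, -(ny - 1) / 2.0 * voxel, -(nz - 1) / 2.0 * voxel)
    x = origin[0] + np.arange(nx) * voxel
    y = origin[1] + np.arange(ny) * voxel
    z = origin[2] + np.arange(nz) * voxel
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    body = ((X / ax) ** 2 + (Y / ay) ** 2 <= 1.0) & (np.abs(Z) <= THORAX_HALF_LENGTH)
    values = np.where(body, 1.0, 0.0)
    lx, ly, lz = THORAX_LUNG_SEMI
    for cx, cy, cz in THORAX_LUNG_CENTERS:
        lung = ((X - cx) / lx) ** 2 + ((Y - cy) / ly) ** 2 + ((Z - cz) / lz) ** 2 <= 1.0
        values = np.where(lung & body, THORAX_LUNG_RED, values)
    return REDVolume(values=values, voxel_size=(voxel, voxel, voxel), origin=origin)


def thorax_analytic_ap_thickness(x: float) -> float:
    """Water-equivalent thickness of a vertical (AP) ray at lateral x.

    Body chord minus lung chords plus lung chords times lung RED, from
    the documented ellipse/ellipsoid geometry (ray in the z = 0 plane).
    """
    ax, ay = THORAX_BODY_SEMI
    if abs(x) >= ax:
        return 0.0
    body = 2.0 * ay * np.sqrt(1.0 - (x / ax) ** 2)
    t = body
    lx, ly, _ = THORAX_LUNG_SEMI
    for cx, _cy, _cz in THORAX_LUNG_CENTERS:
        u = (x - cx) / lx
        if abs(u) < 1.0:
            chord = 2.0 * ly * np.sqrt(1.0 - u**2)
            t += chord * (THORAX_LUNG_RED - 1.0)
    return float(t)


# ---------------------------------------------------------------------------
# plans

def _square_cp(index, frac, fs, offset, gantry):
    half = fs / 2.0
    bank_a = np.full(N_LEAF_PAIRS, offset)
    bank_b = np.full(N_LEAF_PAIRS, offset)
    active = (LEAF_EDGES_CM[1:] > -half) & (LEAF_EDGES_CM[:-1] < half)
    bank_a[active] = offset + half
    bank_b[active] = offset - half
    return ControlPoint(
        index=index,
        gantry_angle=gantry % 360.0,
        cumulative_mu_fraction=frac,
        bank_a_positions=bank_a,
        bank_b_positions=bank_b,
        jaw_x1=offset - half,
        jaw_x2=offset + half,
        jaw_y1=-half,
        jaw_y2=half,
    )


def make_square_field_plan(
    fs: float,
    mu: float = 100.0,
    center_offset_r: float = 0.0,
    gantry: float = 0.0,
) -> TreatmentPlan:
    """Static 2-control-point square field, optionally offset in x.

    The off-axis commissioning geometry is realized by moving the
    MLC/jaw aperture laterally by ``center_offset_r`` (cm at the
    isocenter plane) so the field centre lands at off-axis distance
    1.5 * r on the detector.
    """
    if fs <= 0 or fs > 40.0:
        raise ValueError("field size must be in (0, 40] cm")
    cps = [
        _square_cp(0, 0.0, fs, center_offset_r, gantry),
        _square_cp(1, 1.0, fs, center_offset_r, gantry),
    ]
    plan = TreatmentPlan(
        beams=[Beam(total_mu=mu, control_points=cps, technique="imrt", name=f"sq{fs:g}")],
        label=f"square {fs:g} cm offset {center_offset_r:g}",
    )
    validate_plan(plan)
    return plan


def make_modulated_plan(
    kind: str = "imrt",
    n_cp: int = 8,
    seed: int = 0,
    field_size: float = 10.0,
    mu: float = 200.0,
) -> TreatmentPlan:
    """Reproducible pseudo-random sliding-window plan.

    A leaf-pair window of random width sweeps across the field from
    -fs/2 to +fs/2 over the control points; IMRT keeps the gantry at 0,
    VMAT sweeps it monotonically from 30 to 150 degrees.
    """
    if n_cp < 2:
        raise ValueError("need at least 2 control points")
    if kind not in ("imrt", "vmat"):
        raise ValueError("kind must be 'imrt' or 'vmat'")
    rng = np.random.default_rng(seed)
    half = field_size / 2.0
    active = (LEAF_EDGES_CM[1:] > -half) & (LEAF_EDGES_CM[:-1] < half)
    widths = rng.uniform(1.5, 4.5, size=N_LEAF_PAIRS)
    phase = rng.uniform(-0.15, 0.15, size=N_LEAF_PAIRS)
    gantries = np.linspace(30.0, 150.0, n_cp) if kind == "vmat" else np.zeros(n_cp)
    cps = []
    for i in range(n_cp):
        f = i / (n_cp - 1)
        centers = -half + (f + phase) * field_size
        bank_a = np.zeros(N_LEAF_PAIRS)
        bank_b = np.zeros(N_LEAF_PAIRS)
        bank_a[active] = np.clip(centers[active] + widths[active] / 2, -half, half)
        bank_b[active] = np.clip(centers[active] - widths[active] / 2, -half, half)
        bank_b = np.minimum(bank_b, bank_a)
        cps.append(
            ControlPoint(
                index=i,
                gantry_angle=gantries[i] % 360.0,
                cumulative_mu_fraction=f,
                bank_a_positions=bank_a,
                bank_b_positions=bank_b,
                jaw_x1=-half,
                jaw_x2=half,
                jaw_y1=-half,
                jaw_y2=half,
            )
        )
    plan = TreatmentPlan(
        beams=[Beam(total_mu=mu, control_points=cps, technique=kind, name=f"{kind}-{seed}")],
        label=f"synthetic {kind} seed {seed}",
    )
    validate_plan(plan)
    return plan


# ---------------------------------------------------------------------------
# error catalogue

ERROR_KINDS = (
    "mu_scale",
    "setup_shift",
    "mlc_open",
    "mlc_shift_both",
    "mlc_shift_bank",
    "mlc_central_open",
    "gantry_offset",
)


@dataclass
class ErrorSpec:
    """One deliberate plan/setup perturbation for sensitivity testing."""

    kind: str
    magnitude: float  # %, mm or degrees depending on kind
    direction: str = ""  # for setup_shift: "lateral" | "anterior"

    def __post_init__(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.magnitude == 0:
            raise ValueError("a perturbation needs a non-zero magnitude")


def error_catalogue() -> dict[str, ErrorSpec]:
    """The e1-e17 sensitivity catalogue.

    MU scalings of +1/+3/+5/+10/-5% (e1-e5); 5/10/20 mm phantom shifts
    laterally (e6-e8) and anteriorly (e9-e11); MLC apertures opened
    5 mm (e12), both banks shifted 5 mm (e13), in-field bank-B leaves
    shifted 5 mm (e14), central four pairs opened 10 mm (e15); gantry
    offsets of +5 and +10 degrees (e16-e17).
    """
    cat = {
        "e1": ErrorSpec("mu_scale", 1.0),
        "e2": ErrorSpec("mu_scale", 3.0),
        "e3": ErrorSpec("mu_scale", 5.0),
        "e4": ErrorSpec("mu_scale", 10.0),
        "e5": ErrorSpec("mu_scale", -5.0),
        "e6": ErrorSpec("setup_shift", 5.0, "lateral"),
        "e7": ErrorSpec("setup_shift", 10.0, "lateral"),
        "e8": ErrorSpec("setup_shift", 20.0, "lateral"),
        "e9": ErrorSpec("setup_shift", 5.0, "anterior"),
        "e10": ErrorSpec("setup_shift", 10.0, "anterior"),
        "e11": ErrorSpec("setup_shift", 20.0, "anterior"),
        "e12": ErrorSpec("mlc_open", 5.0),
        "e13": ErrorSpec("mlc_shift_both", 5.0),
        "e14": ErrorSpec("mlc_shift_bank", 5.0),
        "e15": ErrorSpec("mlc_central_open", 10.0),
        "e16": ErrorSpec("gantry_offset", 5.0),
        "e17": ErrorSpec("gantry_offset", 10.0),
    }
    return cat


def inject_error(plan: TreatmentPlan, spec: ErrorSpec) -> TreatmentPlan:
    """Return a perturbed copy of the plan (setup shifts act on the
    phantom, not the plan, and are handled by the simulator)."""
    if spec.kind == "setup_shift":
        return plan  # applied to the volume by simulate_measured_image
    new_beams = []
    for beam in plan.beams:
        total_mu = beam.total_mu
        if spec.kind == "mu_scale":
            total_mu = beam.total_mu * (1.0 + spec.magnitude / 100.0)
        cps = []
        for cp in beam.control_points:
            a = cp.bank_a_positions.copy()
            b = cp.bank_b_positions.copy()
            gantry = cp.gantry_angle
            cm = spec.magnitude / 10.0  # mm -> cm
            if spec.kind == "mlc_open":
                # total aperture widening: half the magnitude per bank
                a = a + cm / 2.0
                b = b - cm / 2.0
            elif spec.kind == "mlc_shift_both":
                a = a + cm
                b = b + cm
            elif spec.kind == "mlc_shift_bank":
                in_field = (a - b > 1e-6) & (LEAF_EDGES_CM[1:] > cp.jaw_y1) & (
                    LEAF_EDGES_CM[:-1] < cp.jaw_y2
                )
                b = np.where(in_field, b + cm, b)
                b = np.minimum(b, a)
            elif spec.kind == "mlc_central_open":
                central = slice(N_LEAF_PAIRS // 2 - 2, N_LEAF_PAIRS // 2 + 2)
                a[central] += cm / 2.0
                b[central] -= cm / 2.0
            elif spec.kind == "gantry_offset":
                gantry = (gantry + spec.magnitude) % 360.0
            if np.any(a - b > 20.0):
                raise ValueError("perturbation exceeds leaf carriage span")
            cps.append(
                replace(
                    cp,
                    gantry_angle=gantry,
                    bank_a_positions=a,
                    bank_b_positions=b,
                )
            )
        new_beams.append(
            Beam(
                total_mu=total_mu,
                control_points=cps,
                isocenter=beam.isocenter,
                technique=beam.technique,
                name=beam.name,
            )
        )
    return TreatmentPlan(beams=new_beams, label=plan.label + f" ({spec.kind}{spec.magnitude:+g})")


# ---------------------------------------------------------------------------
# simulated measurements

def simulate_measured_image(
    plan: TreatmentPlan,
    volume: REDVolume | None,
    truth: TruthModel,
    config: PredictConfig,
    error: ErrorSpec | None = None,
    seed: int | None = None,
) -> PortalImage:
    """Deliver a (possibly perturbed) plan in silico under the truth model.

    The perturbation is applied to the plan, the gantry or the phantom
    placement; the forward model then runs under the truth database and
    seeded Gaussian noise (sigma = ``truth.noise_sigma_pct`` % of the
    local signal) is added.  With no error and zero noise the result
    equals :func:`predict_transmission` under the same database
    bit-for-bit.
    """
    if error is not None:
        if error.kind == "setup_shift":
            if volume is None:
                raise ValueError("setup shift requires a phantom volume")
            cm = error.magnitude / 10.0
            if error.direction == "lateral":
                volume = volume.shifted((cm, 0.0, 0.0))
            elif error.direction == "anterior":
                volume = volume.shifted((0.0, cm, 0.0))
            else:
                raise ValueError(f"unknown shift direction {error.direction!r}")
        else:
            plan = inject_error(plan, error)
    result = predict_transmission(plan, volume, truth.db, config)
    img = result.predicted
    if truth.noise_sigma_pct > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        noise = rng.standard_normal(img.values.shape)
        img = PortalImage(
            values=img.values * (1.0 + truth.noise_sigma_pct / 100.0 * noise),
            grid=img.grid,
            kind=img.kind,
            integrated_mu=img.integrated_mu,
        )
    return img


# ---------------------------------------------------------------------------
# commissioning dataset

@dataclass
class SyntheticMeasurementSpec:
    """Grids and acquisition settings for the commissioning dataset."""

    fs: np.ndarray = field(default_factory=lambda: FS_GRID.copy())
    t: np.ndarray = field(default_factory=lambda: T_GRID.copy())
    r: np.ndarray = field(default_factory=lambda: R_GRID.copy())
    L: np.ndarray = field(default_factory=lambda: L_GRID.copy())
    mu: float = 100.0
    noise_sigma_pct: float = 0.0
    patch: int = 5  # pixels per side of the stored reading patch


def _patch_record(value, fs, t, L, r, mu, patch, pitch) -> MeasurementRecord:
    g = ImageGrid(nx=patch, ny=patch, pitch=pitch)
    img = PortalImage(values=np.full((patch, patch), value), grid=g, kind="open" if t == 0 and not np.isfinite(L) else "transmission")
    return MeasurementRecord(
        image=img, field_size=fs, thickness=t, air_gap=L, offset_r=r, mu=mu
    )


def make_commissioning_dataset(
    truth: TruthModel,
    spec: SyntheticMeasurementSpec | None = None,
    seed: int = 0,
) -> MeasurementSet:
    """Simulate the full commissioning measurement grid.

    Each record stores the grayscale reading at the measurement point
    (the field-centre ROI value a physicist would extract, kept as a
    small uniform patch) plus the setup metadata; ``offset_r`` is the
    detector-plane off-axis distance of the measurement point, realized
    on the machine by moving the MLC aperture laterally by r / 1.5 at
    the isocenter plane.  Open records cover every (fs, r);
    transmission records cover every (fs, t, r, L).  Readings follow
    the truth model:

        open:         G0  = (A*mu + B) * HCM(r) * GFO(fs, r)
        transmission: Gtr = P(r) * T(t, r) * (1 + SPR(L, fs, t, r))

    with P(r) the open primary (A*mu + B) * HCM(r).  Optional Gaussian
    noise (``spec.noise_sigma_pct`` % of each reading) is seeded and
    reproducible.
    """
    spec = spec or SyntheticMeasurementSpec()
    db = truth.db
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []
    pitch = 0.1
    for r in spec.r:
        primary = (db.response.A * spec.mu + db.response.B) * float(db.hcm(r))
        for fs in spec.fs:
            g0 = primary * float(db.gfo(fs, r))
            records.append(
                _patch_record(g0, float(fs), 0.0, np.nan, float(r), spec.mu, spec.patch, pitch)
            )
        for t in spec.t:
            T = float(db.attenuation.transmission(t, r))
            for L in spec.L:
                for fs in spec.fs:
                    spr = float(db.spr(L, fs, t, r))
                    gtr = primary * T * (1.0 + spr)
                    records.append(
                        _patch_record(
                            gtr, float(fs), float(t), float(L), float(r), spec.mu, spec.patch, pitch
                        )
                    )
    if spec.noise_sigma_pct > 0:
        for rec in records:
            rec.image.values *= 1.0 + spec.noise_sigma_pct / 100.0 * rng.standard_normal()
    return MeasurementSet(records=records)


def expected_record_count(spec: SyntheticMeasurementSpec | None = None) -> int:
    """|fs|*|r| open records plus |fs|*|t|*|r|*|L| transmission records."""
    spec = spec or SyntheticMeasurementSpec()
    n_open = spec.fs.size * spec.r.size
    n_trans = spec.fs.size * spec.t.size * spec.r.size * spec.L.size
    return n_open + n_trans


def make_kernel_fit_images(
    truth: TruthModel,
    grid: ImageGrid,
    fs_list=(5.0, 10.0, 15.0, 20.0),
    mu: float = 100.0,
) -> tuple[list[PortalImage], list[FluenceMap]]:
    """Measured-open-image / planned-fluence pairs for the kernel fit."""
    images, fluences = [], []
    for fs in fs_list:
        plan = make_square_field_plan(fs, mu=mu)
        psi = beam_fluence(plan.beams[0], grid)
        psi = FluenceMap(values=psi.values * mu, grid=grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            img = compute_open_image(psi, truth.db.kernel, truth.db.response, truth.db.hcm)
        images.append(img)
        fluences.append(psi)
    return images, fluences


def make_hcm_image(truth: TruthModel, grid: ImageGrid, mu: float = 100.0) -> PortalImage:
    """Simulated open 20 x 20 cm2 image for horn-profile extraction."""
    plan = make_square_field_plan(20.0, mu=mu)
    psi = beam_fluence(plan.beams[0], grid)
    psi = FluenceMap(values=psi.values * mu, grid=grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_open_image(psi, truth.db.kernel, truth.db.response, truth.db.hcm)


def make_response_series(
    truth: TruthModel,
    mu_values=(1, 2, 5, 10, 20, 50, 100, 200, 300, 400, 500, 600),
    noise_sigma_pct: float = 0.0,
    seed: int = 0,
):
    """Central-axis 10 x 10 grayscale readings across the MU range."""
    mu = np.asarray(mu_values, dtype=float)
    g = truth.db.response.A * mu + truth.db.response.B
    if noise_sigma_pct > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + noise_sigma_pct / 100.0 * rng.standard_normal(mu.size))
    return mu, g
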