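"""Commissioning: fit every model parameter from measurement sets.

The commissioning chain mirrors how the detector is characterised on
the machine:

1. a 10 x 10 cm2 field at MU settings from 1 to 600 gives the linear
   response G = A*psi + B (ordinary least squares);
2. a flood-corrected 20 x 20 cm2 open image, normalized to the central
   axis, yields the horn correction profile along the diagonal;
3. open images of 5/10/15/20 cm square fields drive a nonlinear fit of
   the penumbra and detector-scatter kernel shapes;
4. open square fields of 3-20 cm, delivered on and off axis, give the
   global field output factor: per off-axis bin, the grayscale is
   extrapolated to zero field size (quadratic least squares in fs) to
   isolate the primary, and GFO = total / primary;
5. transmission fields through 0-40 cm of solid water give the primary
   transmission per off-axis distance, fitted with the thickness-
   saturated exponential T = exp(-a*t/(1+b*t));
6. the same transmission grid, spanning air gaps of 20-50 cm, yields
   the 4-D scatter-to-primary table SPR(L, fs, t, r) = total/primary - 1
   with the primary again taken from the zero-field extrapolation.

Monotonicity violations in fitted tables are reported, never silently
fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .database import AttenuationTable, GFOTable, ParameterDatabase, SPRTable
from .forward import (
    HornCorrectionMap,
    KernelParams,
    PortalImage,
    ResponseFunction,
    compute_open_image,
    convolve_kernels,
)
from .grid import ImageGrid
from .plan import FluenceMap


class CommissioningError(RuntimeError):
    pass


@dataclass
class MeasurementRecord:
    """One acquisition: an image plus its setup metadata."""

    image: PortalImage
    field_size: float  # cm, equivalent square
    thickness: float  # cm solid water (0 for open fields)
    air_gap: float  # cm exit-to-detector gap (nan for open fields)
    offset_r: float  # cm lateral offset of the field centre
    mu: float = 100.0

    @property
    def reading(self) -> float:
        """Grayscale at the measurement point (image centre ROI)."""
        v = self.image.values
        cj, ci = v.shape[0] // 2, v.shape[1] // 2
        return float(v[cj, ci])

    @property
    def is_open(self) -> bool:
        return self.thickness == 0.0 and not np.isfinite(self.air_gap)


@dataclass
class MeasurementSet:
    records: list[MeasurementRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def select(self, **conditions) -> list[MeasurementRecord]:
        out = []
        for rec in self.records:
            ok = True
            for key, val in conditions.items():
                got = getattr(rec, key)
                if isinstance(val, float) or isinstance(val, int):
                    ok &= abs(got - val) < 1e-9
                else:
                    ok &= got == val
            if ok:
                out.append(rec)
        return out

    @property
    def opens(self) -> list[MeasurementRecord]:
        return [r for r in self.records if r.is_open]

    @property
    def transmissions(self) -> list[MeasurementRecord]:
        return [r for r in self.records if not r.is_open]


# ---------------------------------------------------------------------------
# response

def fit_response(mu_values, grayscale_values) -> ResponseFunction:
    """Ordinary least-squares line grayscale = A * fluence + B.

    Fluence is proportional to MU at fixed field, with one fluence unit
    per MU, so A carries grayscale-per-MU units.
    """
    mu = np.asarray(mu_values, dtype=float)
    g = np.asarray(grayscale_values, dtype=float)
    if mu.size != g.size or np.unique(mu).size < 2:
        raise CommissioningError("need at least two distinct MU settings")
    coeffs, res, *_ = np.polyfit(mu, g, 1, full=True)
    rms = float(np.sqrt(res[0] / mu.size)) if res.size else 0.0
    return ResponseFunction(A=float(coeffs[0]), B=float(coeffs[1]), residual_rms=rms)


# ---------------------------------------------------------------------------
# horn correction

def extract_hcm(open_20x20: PortalImage, r_max: float = 14.0, r_step: float = 0.5) -> HornCorrectionMap:
    """Horn profile from a 20 x 20 cm2 open image.

    The image is normalized to its central-axis value and sampled along
    the main diagonal at ``r_step`` spacing out to ``r_max`` cm; the
    profile is pinned to exactly 1 at r = 0.
    """
    grid = open_20x20.grid
    v = open_20x20.values

    def sample(x: float, y: float) -> float:
        """Bilinear image value at detector position (x, y) cm."""
        jj = np.clip((y / grid.pitch) + (grid.ny - 1) / 2, 0, grid.ny - 1)
        ii = np.clip((x / grid.pitch) + (grid.nx - 1) / 2, 0, grid.nx - 1)
        j0, i0 = int(jj), int(ii)
        fj, fi = jj - j0, ii - i0
        j1, i1 = min(j0 + 1, grid.ny - 1), min(i0 + 1, grid.nx - 1)
        return float(
            v[j0, i0] * (1 - fj) * (1 - fi)
            + v[j0, i1] * (1 - fj) * fi
            + v[j1, i0] * fj * (1 - fi)
            + v[j1, i1] * fj * fi
        )

    # normalization point is the exact central axis (an even grid has
    # no pixel centre there)
    center = sample(0.0, 0.0)
    if center <= 0:
        raise CommissioningError("central-axis value must be positive")
    radii = np.arange(0.0, r_max + r_step / 2, r_step)
    # diagonal direction (1,1)/sqrt(2); average the two opposite
    # diagonals for robustness to noise
    ux = radii / np.sqrt(2.0)
    vals = np.array(
        [0.5 * (sample(u, u) + sample(-u, -u)) / center for u in ux]
    )
    vals[0] = 1.0
    return HornCorrectionMap(radii=radii, factors=vals)


# ---------------------------------------------------------------------------
# kernels

def fit_kernels(
    measured_opens: list[PortalImage],
    fluences: list[FluenceMap],
    response: ResponseFunction,
    hcm: HornCorrectionMap,
    initial: KernelParams | None = None,
    max_nfev: int = 400,
) -> KernelParams:
    """Fit kernel shape parameters to measured open square fields.

    Minimizes the summed squared difference between the forward-model
    open image and the measurement over all pixels, normalized per
    field to its central value so every field size carries comparable
    weight.  Because discrete kernels are unit-normalized, only shapes
    are identifiable: sigma for k1, and for k2 the rates b_i plus the
    relative 2-D mass of each exponential component.  The fit therefore
    parameterizes k2 as a three-component mixture with mass fractions
    (w1, w2, w3) summing to 1 — far better conditioned than raw
    amplitudes, which span several orders of magnitude — and converts
    back through a_i = w_i * b_i^2 (the continuous 2-D mass of
    a*exp(-b*r) is 2*pi*a/b^2).
    """
    if len(measured_opens) != len(fluences) or not measured_opens:
        raise CommissioningError("need matching open images and fluence maps")
    grid = measured_opens[0].grid
    norms = []
    for img in measured_opens:
        cj, ci = grid.ny // 2, grid.nx // 2
        norms.append(float(img.values[cj, ci]))

    def unpack(x) -> KernelParams:
        sigma, w2, w3 = x[0], x[1], x[2]
        b1, b2, b3 = 10.0 ** x[3], 10.0 ** x[4], 10.0 ** x[5]
        w1 = max(1.0 - w2 - w3, 1e-9)
        return KernelParams(
            c=1.0, sigma=sigma,
            a=(w1 * b1**2, w2 * b2**2, w3 * b3**2),
            b=(b1, b2, b3),
        )

    hcm_map = hcm(grid.r)
    # fit only where the horn profile is actually commissioned; beyond
    # its last radial sample the clamped profile is not a model of the
    # measurement
    region = grid.r <= hcm.radii[-1]

    def residuals(x):
        kp = unpack(x)
        res = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for img, psi, norm in zip(measured_opens, fluences, norms):
                pred = response(convolve_kernels(psi.values, kp, grid.pitch)) * hcm_map
                res.append(((pred - img.values)[region] / norm).ravel())
        return np.concatenate(res)

    if initial is not None:
        masses = np.array([ai / bi**2 for ai, bi in zip(initial.a, initial.b)])
        masses /= masses.sum()
        x0 = np.array(
            [
                initial.sigma,
                masses[1],
                masses[2],
                np.log10(initial.b[0]),
                np.log10(initial.b[1]),
                np.log10(initial.b[2]),
            ]
        )
        starts = [x0]
    else:
        starts = [
            np.array([1.0, 0.05, 0.10, np.log10(15.0), np.log10(5.0), np.log10(0.5)]),
            np.array([2.0, 0.10, 0.25, np.log10(30.0), np.log10(8.0), np.log10(1.0)]),
        ]
    lb = np.array([0.05, 0.0, 0.0, np.log10(0.05), np.log10(0.05), np.log10(0.05)])
    ub = np.array([5.0, 1.0, 1.0, np.log10(200.0), np.log10(200.0), np.log10(50.0)])
    best = None
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=(lb, ub), max_nfev=max_nfev, x_scale="jac"
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-12:
            break
    if best is None or not np.all(np.isfinite(best.x)):
        raise CommissioningError("kernel fit failed to converge")
    kp = unpack(best.x)
    kp.objective = float(best.cost)  # type: ignore[attr-defined]
    return kp


# ---------------------------------------------------------------------------
# zero-field extrapolation

def extrapolate_zero_field(fs_values, grayscale_values, order: int = 2):
    """Least-squares polynomial extrapolation of grayscale to fs -> 0.

    Fits G(fs) = p0 + p1*fs + ... + p_order*fs^order and returns
    (p0, standard_error_of_p0).  The intercept is the primary
    grayscale: scatter vanishes with the field size.
    """
    fs = np.asarray(fs_values, dtype=float)
    g = np.asarray(grayscale_values, dtype=float)
    if fs.size < order + 1:
        raise CommissioningError(
            f"need at least {order + 1} field sizes for order-{order} extrapolation"
        )
    X = np.vander(fs, order + 1, increasing=True)
    coef, res, rank, _ = np.linalg.lstsq(X, g, rcond=None)
    p0 = float(coef[0])
    if p0 <= 0:
        raise CommissioningError("extrapolated primary grayscale is non-positive")
    dof = fs.size - (order + 1)
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        stderr = float(np.sqrt(cov[0, 0]))
    else:
        stderr = 0.0
    return p0, stderr


def _batched_zero_field(fs: np.ndarray, g: np.ndarray, order: int = 2) -> np.ndarray:
    """Vectorized intercepts of per-cell polynomial fits over axis 0 of g."""
    X = np.vander(fs, order + 1, increasing=True)
    pinv = np.linalg.pinv(X)
    coef = np.tensordot(pinv, g, axes=(1, 0))
    return coef[0]


# ---------------------------------------------------------------------------
# GFO

def compute_gfo(open_set: MeasurementSet, order: int = 2) -> GFOTable:
    """Global field output factors from open square-field readings."""
    opens = open_set.opens if isinstance(open_set, MeasurementSet) else list(open_set)
    if not opens:
        raise CommissioningError("no open-field records")
    r_vals = sorted({round(rec.offset_r, 6) for rec in opens})
    fs_vals = sorted({round(rec.field_size, 6) for rec in opens})
    table = np.empty((len(fs_vals), len(r_vals)))
    for jr, r in enumerate(r_vals):
        readings = []
        for fs in fs_vals:
            recs = [
                rec for rec in opens
                if abs(rec.offset_r - r) < 1e-6 and abs(rec.field_size - fs) < 1e-6
            ]
            if not recs:
                raise CommissioningError(f"missing open field fs={fs} at r={r}")
            readings.append(np.mean([rec.reading for rec in recs]))
        primary, _ = extrapolate_zero_field(fs_vals, readings, order=order)
        table[:, jr] = np.asarray(readings) / primary
    gfo = GFOTable(fs=np.array(fs_vals), r=np.array(r_vals), values=table)
    for v in gfo.violations():
        warnings.warn(f"GFO invariant violation: {v}", stacklevel=2)
    return gfo


# ---------------------------------------------------------------------------
# attenuation

def fit_attenuation(
    transmission_set: MeasurementSet,
    order: int = 2,
    fix_b: float | None = None,
) -> AttenuationTable:
    """Attenuation coefficients (a(r), b(r)) of the primary beam.

    For each off-axis bin the primary grayscale at every thickness is
    isolated by zero-field extrapolation (averaged over the measured
    air gaps, on which the primary does not depend), normalized to the
    t = 0 primary, and fitted with T(t) = exp(-a*t / (1 + b*t)).
    With ``fix_b`` the saturation coefficient is pinned (``fix_b=0``
    reduces the model to a pure exponential) and only a is fitted.
    """
    trans = transmission_set.transmissions if isinstance(transmission_set, MeasurementSet) else list(transmission_set)
    if not trans:
        raise CommissioningError("no transmission records")
    r_vals = sorted({round(rec.offset_r, 6) for rec in trans})
    t_vals = sorted({round(rec.thickness, 6) for rec in trans})
    if 0.0 not in t_vals:
        raise CommissioningError("transmission grid must include t = 0")
    a_out, b_out = [], []
    for r in r_vals:
        primaries = []
        for t in t_vals:
            recs = [
                rec for rec in trans
                if abs(rec.offset_r - r) < 1e-6 and abs(rec.thickness - t) < 1e-6
            ]
            per_gap = {}
            for rec in recs:
                per_gap.setdefault(round(rec.air_gap, 6), []).append(rec)
            p_gaps = []
            for gap_recs in per_gap.values():
                fs = [rec.field_size for rec in gap_recs]
                g = [rec.reading for rec in gap_recs]
                p0, _ = extrapolate_zero_field(fs, g, order=order)
                p_gaps.append(p0)
            primaries.append(float(np.mean(p_gaps)))
        T = np.asarray(primaries) / primaries[t_vals.index(0.0)]
        if np.any(T > 1.0 + 1e-6) or np.any(T <= 0):
            raise CommissioningError(f"unphysical primary transmission at r={r}")

        if fix_b is None:
            def model(t, a, b):
                return np.exp(-a * np.asarray(t) / (1.0 + b * np.asarray(t)))

            popt, _ = curve_fit(
                model, np.asarray(t_vals), T, p0=(0.05, 0.004),
                bounds=([1e-4, 0.0], [1.0, 0.5]), maxfev=10000,
            )
            a_out.append(popt[0])
            b_out.append(popt[1])
        else:
            def model_a(t, a):
                return np.exp(-a * np.asarray(t) / (1.0 + fix_b * np.asarray(t)))

            popt, _ = curve_fit(
                model_a, np.asarray(t_vals), T, p0=(0.05,),
                bounds=([1e-4], [1.0]), maxfev=10000,
            )
            a_out.append(popt[0])
            b_out.append(fix_b)
    table = AttenuationTable(r=np.array(r_vals), a=np.array(a_out), b=np.array(b_out))
    for v in table.violations():
        warnings.warn(f"attenuation invariant violation: {v}", stacklevel=2)
    return table


# ---------------------------------------------------------------------------
# SPR

def compute_spr(transmission_set: MeasurementSet, order: int = 2) -> SPRTable:
    """4-D scatter-to-primary table from the transmission grid.

    Per (L, t, r) cell the readings across field size are extrapolated
    to fs -> 0 (the primary); SPR(fs) = total/primary - 1.  Cells whose
    extrapolated primary is non-positive are marked invalid (NaN) and
    reported.
    """
    trans = transmission_set.transmissions if isinstance(transmission_set, MeasurementSet) else list(transmission_set)
    if not trans:
        raise CommissioningError("no transmission records")
    L_vals = np.array(sorted({round(rec.air_gap, 6) for rec in trans}))
    fs_vals = np.array(sorted({round(rec.field_size, 6) for rec in trans}))
    t_vals = np.array(sorted({round(rec.thickness, 6) for rec in trans}))
    r_vals = np.array(sorted({round(rec.offset_r, 6) for rec in trans}))
    G = np.full((L_vals.size, fs_vals.size, t_vals.size, r_vals.size), np.nan)
    index = {
        (round(rec.air_gap, 6), round(rec.field_size, 6), round(rec.thickness, 6), round(rec.offset_r, 6)): rec
        for rec in trans
    }
    for iL, L in enumerate(L_vals):
        for ifs, fs in enumerate(fs_vals):
            for it, t in enumerate(t_vals):
                for ir, r in enumerate(r_vals):
                    rec = index.get((round(L, 6), round(fs, 6), round(t, 6), round(r, 6)))
                    if rec is None:
                        raise CommissioningError(
                            f"missing transmission record L={L} fs={fs} t={t} r={r}"
                        )
                    G[iL, ifs, it, ir] = rec.reading
    primary = _batched_zero_field(fs_vals, np.moveaxis(G, 1, 0), order=order)
    invalid = primary <= 0
    if np.any(invalid):
        warnings.warn(
            f"{int(np.count_nonzero(invalid))} SPR cells have non-positive "
            "extrapolated primary; marked invalid",
            stacklevel=2,
        )
        primary = np.where(invalid, np.nan, primary)
    spr_values = G / primary[:, None, :, :] - 1.0
    table = SPRTable(L=L_vals, fs=fs_vals, t=t_vals, r=r_vals, values=spr_values)
    for v in table.violations():
        warnings.warn(f"SPR invariant violation: {v}", stacklevel=2)
    return table


# ---------------------------------------------------------------------------
# equivalent square

def equivalent_square(aperture, pitch: float | None = None, magnification: float = 1.5):
    """Equivalent square field size, cm at the isocenter plane.

    For a rectangle (w, h): the classic 2wh/(w+h).  For a fluence map
    or a 2-D array (with ``pitch`` in cm at the detector plane): the
    Sterling 4*Area/Perimeter of the region above half the map maximum,
    rescaled to the isocenter plane by ``magnification``.
    Returns 0.0 for an empty aperture.
    """
    if isinstance(aperture, tuple) and len(aperture) == 2:
        w, h = aperture
        if w <= 0 or h <= 0:
            return 0.0
        return 2.0 * w * h / (w + h)
    if isinstance(aperture, FluenceMap):
        values = aperture.values
        pitch = aperture.grid.pitch
    else:
        values = np.asarray(aperture, dtype=float)
        if pitch is None:
            raise ValueError("pitch required for raw-array apertures")
    vmax = values.max() if values.size else 0.0
    if vmax <= 0:
        return 0.0
    mask = values > 0.5 * vmax
    area = np.count_nonzero(mask)
    if area == 0:
        return 0.0
    # perimeter = count of exposed pixel edges
    padded = np.pad(mask, 1)
    perim = (
        np.count_nonzero(padded[1:, :] != padded[:-1, :])
        + np.count_nonzero(padded[:, 1:] != padded[:, :-1])
    )
    p_iso = pitch / magnification
    return 4.0 * (area * p_iso**2) / (perim * p_iso)


# ---------------------------------------------------------------------------
# one-call commissioning

def commission(
    measurement_set: MeasurementSet,
    kernel_opens: list[PortalImage],
    kernel_fluences: list[FluenceMap],
    hcm_image: PortalImage,
    response_mu,
    response_grayscale,
    metadata: dict | None = None,
) -> ParameterDatabase:
    """Run the full commissioning chain and assemble the database."""
    response = fit_response(response_mu, response_grayscale)
    hcm = extract_hcm(hcm_image)
    kernel = fit_kernels(kernel_opens, kernel_fluences, response, hcm)
    gfo = compute_gfo(measurement_set)
    attenuation = fit_attenuation(measurement_set)
    spr = compute_spr(measurement_set)
    return ParameterDatabase(
        kernel=kernel,
        response=response,
        hcm=hcm,
        gfo=gfo,
        attenuation=attenuation,
        spr=spr,
        metadata=metadata or {},
    )
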