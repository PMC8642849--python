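"""Commissioning fitters: response, HCM, kernels, GFO, attenuation, SPR."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epidpredict import (
    GFOTable,
    ImageGrid,
    PortalImage,
    compute_gfo,
    compute_spr,
    equivalent_square,
    extract_hcm,
    extrapolate_zero_field,
    fit_attenuation,
    fit_kernels,
    fit_response,
    lookup,
)
from epidpredict.commission import CommissioningError, MeasurementRecord, MeasurementSet
from epidpredict.database import SPRTable
from epidpredict.synthetic import (
    SyntheticMeasurementSpec,
    make_commissioning_dataset,
    make_hcm_image,
    make_kernel_fit_images,
    make_response_series,
    make_truth_model,
)


def _uniform_record(value, fs, t=0.0, L=np.nan, r=0.0):
    g = ImageGrid(nx=5, ny=5, pitch=0.1)
    return MeasurementRecord(
        image=PortalImage(values=np.full((5, 5), float(value)), grid=g),
        field_size=fs, thickness=t, air_gap=L, offset_r=r,
    )


# ---------------------------------------------------------------------------
# response

def test_fit_response_exact_line():
    resp = fit_response([1, 10, 100], [3, 21, 201])
    assert resp.A == pytest.approx(2.0)
    assert resp.B == pytest.approx(1.0)


def test_fit_response_recovers_detector_line(truth):
    mu, g = make_response_series(truth)
    resp = fit_response(mu, g)
    assert resp.A == pytest.approx(truth.db.response.A, rel=1e-12)
    assert resp.B == pytest.approx(truth.db.response.B, rel=1e-6)


def test_fit_response_with_noise_monte_carlo(truth):
    mu = np.linspace(10, 600, 20)
    rng = np.random.default_rng(0)
    g = (truth.db.response.A * mu + truth.db.response.B) * (1 + 0.05 * rng.standard_normal(20))
    resp = fit_response(mu, g)
    assert abs(resp.A - truth.db.response.A) / truth.db.response.A < 0.05


def test_fit_response_rejects_single_mu():
    with pytest.raises(CommissioningError):
        fit_response([100, 100], [1, 1])


# ---------------------------------------------------------------------------
# HCM

def test_extract_hcm_flat_image(grid16):
    img = PortalImage(values=np.ones(grid16.shape), grid=grid16)
    hcm = extract_hcm(img)
    np.testing.assert_allclose(hcm.factors, 1.0, atol=1e-9)


def test_extract_hcm_reads_radial_profile():
    # odd grid: a pixel sits exactly on the central axis, so the
    # conical profile 1 + 0.02 r reads back without interpolation bias
    grid = ImageGrid(nx=65, ny=65, pitch=0.5)
    img = PortalImage(values=1.0 + 0.02 * grid.r, grid=grid)
    hcm = extract_hcm(img)
    assert hcm(5.0) == pytest.approx(1.10, abs=2e-3)
    assert hcm(0.0) == 1.0


def test_extract_hcm_symmetric_under_diagonal_choice(grid16):
    img = PortalImage(values=1.0 + 0.001 * grid16.r**2, grid=grid16)
    hcm = extract_hcm(img)
    flipped = PortalImage(values=img.values[::-1, :].copy(), grid=grid16)
    hcm2 = extract_hcm(flipped)
    np.testing.assert_allclose(hcm.factors, hcm2.factors, atol=1e-9)


def test_extract_hcm_requires_positive_center(grid16):
    img = PortalImage(values=np.zeros(grid16.shape), grid=grid16)
    with pytest.raises(CommissioningError):
        extract_hcm(img)


# ---------------------------------------------------------------------------
# kernels (module-scoped fit shared by several assertions)

@pytest.fixture(scope="module")
def kernel_fit(truth, grid8):
    opens, fluences = make_kernel_fit_images(truth, grid8)
    hcm = extract_hcm(make_hcm_image(truth, grid8))
    mu, g = make_response_series(truth)
    resp = fit_response(mu, g)
    kp = fit_kernels(opens, fluences, resp, hcm)
    return kp, opens, fluences, resp, hcm


def test_fit_kernels_recovers_sigma(kernel_fit, truth):
    kp, *_ = kernel_fit
    assert abs(kp.sigma - truth.db.kernel.sigma) / truth.db.kernel.sigma < 0.02


def test_fit_kernels_profile_rms(kernel_fit, grid8):
    from epidpredict.forward import convolve_kernels

    kp, opens, fluences, resp, hcm = kernel_fit
    region = grid8.r <= hcm.radii[-1]
    cj, ci = grid8.ny // 2, grid8.nx // 2
    for img, psi in zip(opens, fluences):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = resp(convolve_kernels(psi.values, kp, grid8.pitch)) * hcm(grid8.r)
        rms = np.sqrt(np.mean((pred - img.values)[region] ** 2)) / img.values[cj, ci]
        assert rms < 0.005


def test_fit_kernels_from_truth_is_fixed_point(truth, grid8, kernel_fit):
    """Starting at the generating parameters the optimizer stays put:
    sigma barely moves and the objective is no worse than the
    generic-start fit's (the small floor comes from the commissioned
    horn profile, which is itself extracted from a sampled image)."""
    generic_kp, opens, fluences, resp, hcm = kernel_fit
    kp = fit_kernels(opens, fluences, resp, hcm, initial=truth.db.kernel, max_nfev=60)
    assert abs(kp.sigma - truth.db.kernel.sigma) / truth.db.kernel.sigma < 0.005
    assert kp.objective <= generic_kp.objective * 1.5


def test_fit_kernels_tolerates_mild_noise(truth, grid8, kernel_fit):
    from epidpredict.forward import convolve_kernels

    _, opens, fluences, resp, hcm = kernel_fit
    rng = np.random.default_rng(3)
    noisy = [
        PortalImage(values=img.values * (1 + 0.01 * rng.standard_normal(img.values.shape)),
                    grid=img.grid)
        for img in opens
    ]
    kp = fit_kernels(noisy, fluences, resp, hcm)
    region = grid8.r <= hcm.radii[-1]
    cj, ci = grid8.ny // 2, grid8.nx // 2
    for img, psi in zip(opens, fluences):  # compare against noiseless truth images
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = resp(convolve_kernels(psi.values, kp, grid8.pitch)) * hcm(grid8.r)
        rms = np.sqrt(np.mean((pred - img.values)[region] ** 2)) / img.values[cj, ci]
        assert rms < 0.015


# ---------------------------------------------------------------------------
# zero-field extrapolation

def test_extrapolate_constant():
    p0, _ = extrapolate_zero_field([3, 5, 10], [1000.0, 1000.0, 1000.0])
    assert p0 == pytest.approx(1000.0)


def test_extrapolate_exact_quadratic():
    fs = np.array([3, 5, 8, 10, 15, 20], dtype=float)
    g = 1000.0 + 20.0 * fs + 0.5 * fs**2
    p0, stderr = extrapolate_zero_field(fs, g)
    assert p0 == pytest.approx(1000.0, abs=1e-8)
    assert stderr == pytest.approx(0.0, abs=1e-6)


def test_extrapolate_saturating_model_mismatch_small_fields():
    fs = np.array([3.0, 4.0, 5.0])
    gp = 500.0
    g = gp * (1.0 + 0.3 * (1.0 - np.exp(-fs / 8.0)))  # saturating output factor
    p0, _ = extrapolate_zero_field(fs, g)
    assert abs(p0 - gp) / gp < 0.01


def test_extrapolate_rejects_nonpositive_primary():
    with pytest.raises(CommissioningError):
        extrapolate_zero_field([3, 5, 8, 10], [10.0, 200.0, 500.0, 800.0])


# ---------------------------------------------------------------------------
# GFO / attenuation / SPR round-trips

@pytest.fixture(scope="module")
def dataset(truth):
    return make_commissioning_dataset(truth)


def test_compute_gfo_recovers_truth(dataset, truth):
    gfo = compute_gfo(dataset)
    np.testing.assert_allclose(gfo.values, truth.db.gfo.values, atol=1e-3)


def test_gfo_scale_invariance(dataset):
    gfo = compute_gfo(dataset)
    scaled = MeasurementSet(
        records=[
            MeasurementRecord(
                image=PortalImage(values=2.0 * r.image.values, grid=r.image.grid),
                field_size=r.field_size, thickness=r.thickness,
                air_gap=r.air_gap, offset_r=r.offset_r, mu=r.mu,
            )
            for r in dataset.opens
        ]
    )
    gfo2 = compute_gfo(scaled)
    np.testing.assert_allclose(gfo2.values, gfo.values, rtol=1e-12)


def test_gfo_definition_arithmetic():
    fs_list = [3.0, 4.0, 5.0, 8.0, 10.0]
    primary = 1000.0
    records = [_uniform_record(primary * (1.0 + 0.005 * fs), fs) for fs in fs_list]
    gfo = compute_gfo(MeasurementSet(records=records))
    i10 = list(gfo.fs).index(10.0)
    assert gfo.values[i10, 0] == pytest.approx(1.05, abs=1e-9)


def test_fit_attenuation_recovers_reference_coefficients(dataset, truth):
    """Noiseless recovery of the measured-beam coefficients, including
    the central-axis row (a=0.0575, b=0.003642) and the 10 cm row
    (a=0.0640, b=0.005898)."""
    att = fit_attenuation(dataset)
    np.testing.assert_allclose(att.a, truth.db.attenuation.a, rtol=1e-4)
    np.testing.assert_allclose(att.b, truth.db.attenuation.b, rtol=1e-3)
    assert att.a[0] == pytest.approx(0.0575, rel=1e-4)
    assert att.b[0] == pytest.approx(0.003642, rel=1e-3)
    assert att.a[-1] == pytest.approx(0.0640, rel=1e-4)
    assert att.b[-1] == pytest.approx(0.005898, rel=1e-3)


def test_attenuation_pure_exponential_limit():
    """With the saturation coefficient pinned to zero, purely
    exponential data recovers a exactly."""
    t = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
    fs_list = [3.0, 5.0, 8.0]
    records = []
    for ti in t:
        for fs in fs_list:
            records.append(_uniform_record(1000.0 * np.exp(-0.05 * ti), fs, t=ti, L=30.0))
    att = fit_attenuation(MeasurementSet(records=records), fix_b=0.0)
    assert att.a[0] == pytest.approx(0.05, abs=1e-9)
    assert att.b[0] == 0.0


def test_compute_spr_recovers_truth(dataset, truth):
    spr = compute_spr(dataset)
    assert np.nanmax(np.abs(spr.values - truth.db.spr.values)) < 1e-3


def test_compute_spr_linear_case():
    fs_list = [3.0, 5.0, 8.0, 10.0]
    P = 700.0
    records = [
        _uniform_record(P * (1.0 + 0.01 * fs), fs, t=10.0, L=30.0) for fs in fs_list
    ]
    spr = compute_spr(MeasurementSet(records=records))
    i10 = list(spr.fs).index(10.0)
    assert spr.values[0, i10, 0, 0] == pytest.approx(0.10, abs=1e-9)


def test_compute_spr_scatter_free():
    records = [
        _uniform_record(400.0, fs, t=5.0, L=30.0) for fs in [3.0, 5.0, 8.0, 10.0]
    ]
    spr = compute_spr(MeasurementSet(records=records))
    np.testing.assert_allclose(spr.values, 0.0, atol=1e-12)


def test_monotonicity_of_commissioned_tables(dataset):
    """GFO non-decreasing in fs / non-increasing in r; SPR
    non-decreasing in fs and t, non-increasing in r and L; attenuation
    transmission strictly decreasing from T(0)=1."""
    gfo = compute_gfo(dataset)
    assert gfo.violations() == []
    spr = compute_spr(dataset)
    assert spr.violations() == []
    att = fit_attenuation(dataset)
    assert att.violations() == []
    t = np.linspace(0.0, 40.0, 41)
    T = att.transmission(t, 0.0)
    assert T[0] == pytest.approx(1.0)
    assert np.all(np.diff(T) < 0)


# ---------------------------------------------------------------------------
# equivalent square

@pytest.mark.parametrize(
    "dims,expected",
    [((10.0, 10.0), 10.0), ((5.0, 20.0), 8.0), ((0.0, 4.0), 0.0)],
)
def test_equivalent_square_rectangles(dims, expected):
    assert equivalent_square(dims) == pytest.approx(expected)


def test_equivalent_square_single_pixel():
    values = np.zeros((9, 9))
    values[4, 4] = 1.0
    fs = equivalent_square(values, pitch=0.3, magnification=1.0)
    assert fs == pytest.approx(0.3)


def test_equivalent_square_of_rasterized_square(grid8):
    from epidpredict.plan import beam_fluence
    from epidpredict.synthetic import make_square_field_plan

    psi = beam_fluence(make_square_field_plan(10.0).beams[0], grid8)
    assert equivalent_square(psi) == pytest.approx(10.0, abs=2 * grid8.pitch / 1.5)


# ---------------------------------------------------------------------------
# database lookup

def test_lookup_node_and_midpoint(db):
    gfo = db.gfo
    v = lookup(db, "gfo", {"fs": gfo.fs[2], "r": gfo.r[3]})
    assert v == pytest.approx(gfo.values[2, 3], abs=1e-12)
    mid = lookup(db, "gfo", {"fs": (gfo.fs[2] + gfo.fs[3]) / 2, "r": gfo.r[3]})
    assert mid == pytest.approx((gfo.values[2, 3] + gfo.values[3, 3]) / 2, abs=1e-12)


def test_lookup_rejects_nan(db):
    with pytest.raises(ValueError, match="NaN"):
        lookup(db, "spr", {"L": np.nan, "fs": 10.0, "t": 5.0, "r": 0.0})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    L=st.floats(20.0, 50.0),
    fs=st.floats(3.0, 20.0),
    t=st.floats(0.0, 40.0),
    r=st.floats(0.0, 10.0),
)
def test_lookup_matches_nested_1d_interpolation(L, fs, t, r):
    """4-D multilinear lookup equals an independent chain of nested 1-D
    linear interpolations."""
    truth = make_truth_model()
    spr = truth.db.spr

    def nested(L, fs, t, r):
        v = spr.values
        v = np.array([np.interp(L, spr.L, v[:, i, j, k])
                      for i in range(spr.fs.size)
                      for j in range(spr.t.size)
                      for k in range(spr.r.size)]).reshape(spr.fs.size, spr.t.size, spr.r.size)
        v = np.array([np.interp(fs, spr.fs, v[:, j, k])
                      for j in range(spr.t.size)
                      for k in range(spr.r.size)]).reshape(spr.t.size, spr.r.size)
        v = np.array([np.interp(t, spr.t, v[:, k]) for k in range(spr.r.size)])
        return np.interp(r, spr.r, v)

    assert float(spr(L, fs, t, r)) == pytest.approx(nested(L, fs, t, r), abs=1e-12)


def test_lookup_clamps_out_of_grid(db):
    inside = float(db.spr(50.0, 10.0, 5.0, 10.0))
    beyond = float(db.spr(120.0, 10.0, 5.0, 25.0))
    assert beyond == pytest.approx(inside, abs=1e-12)


# ---------------------------------------------------------------------------
# serialization

def test_database_json_round_trip(db, tmp_path):
    from epidpredict import load_database, save_database

    path = tmp_path / "db.json"
    save_database(db, path)
    loaded = load_database(path)
    np.testing.assert_allclose(loaded.spr.values, db.spr.values)
    np.testing.assert_allclose(loaded.gfo.values, db.gfo.values)
    assert loaded.kernel.sigma == db.kernel.sigma
    assert loaded.response.A == db.response.A
    assert loaded.validate() == []
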