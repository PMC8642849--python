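"""Plan loading, validation, up-sampling and fluence rasterization."""

import json

import numpy as np
import pytest

from epidpredict import ImageGrid, load_plan, rasterize_fluence, upsample_control_points, write_plan
from epidpredict.plan import (
    Beam,
    ControlPoint,
    N_LEAF_PAIRS,
    PlanParseError,
    PlanValidationError,
    aperture_coverage,
    beam_fluence,
    validate_plan,
)
from epidpredict.synthetic import make_modulated_plan, make_square_field_plan


def _json_plan_doc(fractions=(0.0, 1.0), gantries=None):
    gantries = gantries or [0.0] * len(fractions)
    cps = []
    for f, g in zip(fractions, gantries):
        cps.append(
            {
                "gantry": g,
                "mu_fraction": f,
                "bank_a": [5.0] * N_LEAF_PAIRS,
                "bank_b": [-5.0] * N_LEAF_PAIRS,
                "jaws": {"x1": -5.0, "x2": 5.0, "y1": -5.0, "y2": 5.0},
            }
        )
    return {"beams": [{"total_mu": 100.0, "control_points": cps}]}


def test_json_round_trip_preserves_all_fields(tmp_path):
    plan = make_modulated_plan("vmat", n_cp=6, seed=3)
    path = tmp_path / "plan.json"
    write_plan(plan, path)
    loaded = load_plan(path, dialect="json")
    assert len(loaded.beams) == len(plan.beams)
    for b0, b1 in zip(plan.beams, loaded.beams):
        assert b1.total_mu == b0.total_mu
        assert b1.technique == b0.technique
        for c0, c1 in zip(b0.control_points, b1.control_points):
            assert c1.gantry_angle == pytest.approx(c0.gantry_angle)
            assert c1.cumulative_mu_fraction == pytest.approx(c0.cumulative_mu_fraction)
            np.testing.assert_array_equal(c1.bank_a_positions, c0.bank_a_positions)
            np.testing.assert_array_equal(c1.bank_b_positions, c0.bank_b_positions)
            assert c1.jaws == c0.jaws


def test_two_cp_fixture_loads_with_fractions_preserved(tmp_path):
    path = tmp_path / "plan.json"
    path.write_text(json.dumps(_json_plan_doc()))
    plan = load_plan(path)
    cps = plan.beams[0].control_points
    assert len(cps) == 2
    assert [c.cumulative_mu_fraction for c in cps] == [0.0, 1.0]


def test_non_monotone_mu_fractions_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(_json_plan_doc(fractions=(0.0, 0.5, 0.4, 1.0))))
    with pytest.raises(PlanValidationError):
        load_plan(path)


def test_bank_crossing_rejected():
    cp = ControlPoint(
        index=0, gantry_angle=0.0, cumulative_mu_fraction=0.0,
        bank_a_positions=np.full(N_LEAF_PAIRS, -1.0),
        bank_b_positions=np.full(N_LEAF_PAIRS, 1.0),
        jaw_x1=-5, jaw_x2=5, jaw_y1=-5, jaw_y2=5,
    )
    cp2 = ControlPoint(
        index=1, gantry_angle=0.0, cumulative_mu_fraction=1.0,
        bank_a_positions=np.full(N_LEAF_PAIRS, -1.0),
        bank_b_positions=np.full(N_LEAF_PAIRS, 1.0),
        jaw_x1=-5, jaw_x2=5, jaw_y1=-5, jaw_y2=5,
    )
    from epidpredict.plan import TreatmentPlan

    with pytest.raises(PlanValidationError):
        validate_plan(TreatmentPlan(beams=[Beam(total_mu=100, control_points=[cp, cp2])]))


def test_missing_mlc_sequence_is_parse_error(tmp_path):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian

    ds = Dataset()
    ds.BeamSequence = []
    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = pydicom.uid.RTPlanStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    ds.file_meta = meta
    beam = Dataset()
    beam.BeamNumber = 1
    cp = Dataset()
    cp.CumulativeMetersetWeight = 0.0
    cp.GantryAngle = 0.0
    cp2 = Dataset()
    cp2.CumulativeMetersetWeight = 1.0
    beam.ControlPointSequence = [cp, cp2]
    beam.FinalCumulativeMetersetWeight = 1.0
    ds.BeamSequence = [beam]
    path = tmp_path / "plan.dcm"
    ds.save_as(path, enforce_file_format=True)
    with pytest.raises(PlanParseError):
        load_plan(path, dialect="dicom")


def test_dicom_plan_round_trips_leaf_positions(tmp_path):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian

    ds = Dataset()
    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = pydicom.uid.RTPlanStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    ds.file_meta = meta
    beam = Dataset()
    beam.BeamNumber = 1
    beam.FinalCumulativeMetersetWeight = 1.0
    cps = []
    for w in (0.0, 1.0):
        cp = Dataset()
        cp.CumulativeMetersetWeight = w
        cp.GantryAngle = 0.0
        mlc = Dataset()
        mlc.RTBeamLimitingDeviceType = "MLCX"
        # bank B at -30 mm, bank A at +40 mm
        mlc.LeafJawPositions = [-30.0] * N_LEAF_PAIRS + [40.0] * N_LEAF_PAIRS
        jx = Dataset()
        jx.RTBeamLimitingDeviceType = "ASYMX"
        jx.LeafJawPositions = [-50.0, 50.0]
        jy = Dataset()
        jy.RTBeamLimitingDeviceType = "ASYMY"
        jy.LeafJawPositions = [-50.0, 50.0]
        cp.BeamLimitingDevicePositionSequence = [jx, jy, mlc]
        cps.append(cp)
    beam.ControlPointSequence = cps
    ds.BeamSequence = [beam]
    path = tmp_path / "plan.dcm"
    ds.save_as(path, enforce_file_format=True)
    plan = load_plan(path, dialect="dicom")
    cp0 = plan.beams[0].control_points[0]
    assert cp0.bank_b_positions[0] == pytest.approx(-3.0)  # cm, negative-x bank
    assert cp0.bank_a_positions[0] == pytest.approx(4.0)
    assert cp0.jaw_x1 == pytest.approx(-5.0)


# ---------------------------------------------------------------------------
# up-sampling

def test_upsample_factor_one_is_identity():
    plan = make_square_field_plan(10.0)
    assert upsample_control_points(plan, 1) is plan


def test_upsample_linearly_interpolates_leaves(tmp_path):
    doc = _json_plan_doc()
    doc["beams"][0]["control_points"][0]["bank_a"] = [0.0] * N_LEAF_PAIRS
    doc["beams"][0]["control_points"][0]["bank_b"] = [-5.0] * N_LEAF_PAIRS
    doc["beams"][0]["control_points"][1]["bank_a"] = [5.0] * N_LEAF_PAIRS
    doc["beams"][0]["control_points"][1]["bank_b"] = [-5.0] * N_LEAF_PAIRS
    path = tmp_path / "p.json"
    path.write_text(json.dumps(doc))
    plan = load_plan(path)
    up = upsample_control_points(plan, 5)
    cps = up.beams[0].control_points
    assert len(cps) == 5 * (2 - 1) + 1
    leaf0 = [cp.bank_a_positions[0] for cp in cps]
    np.testing.assert_allclose(leaf0, [0, 1, 2, 3, 4, 5])
    fracs = [cp.cumulative_mu_fraction for cp in cps]
    np.testing.assert_allclose(fracs, np.linspace(0, 1, 6))


def test_upsample_gantry_shortest_arc_across_zero(tmp_path):
    doc = _json_plan_doc(fractions=(0.0, 1.0), gantries=[358.0, 2.0])
    path = tmp_path / "p.json"
    path.write_text(json.dumps(doc))
    up = upsample_control_points(load_plan(path), 2)
    mid = up.beams[0].control_points[1].gantry_angle
    assert mid == pytest.approx(0.0, abs=1e-12)


def test_upsample_raises_for_bad_factor():
    with pytest.raises(ValueError):
        upsample_control_points(make_square_field_plan(10.0), 0)


# ---------------------------------------------------------------------------
# rasterization

def test_open_field_projects_with_magnification(grid8):
    plan = make_square_field_plan(10.0)  # 10 cm at iso -> 15 cm on panel
    c0, c1 = plan.beams[0].control_points
    psi = rasterize_fluence((c0, c1), grid8)
    X, Y = grid8.mesh()
    interior = (np.abs(X) < 7.0) & (np.abs(Y) < 7.0)
    exterior = (np.abs(X) > 8.0) | (np.abs(Y) > 8.0)
    assert np.all(psi.values[interior] == pytest.approx(1.0))
    assert np.all(psi.values[exterior] == 0.0)
    # delivered MU fraction scales linearly
    c_half = c1
    c_half.cumulative_mu_fraction = 0.25
    psi_q = rasterize_fluence((c0, c_half), grid8)
    assert psi_q.values[interior].max() == pytest.approx(0.25)
    c_half.cumulative_mu_fraction = 1.0


def test_edge_pixel_gets_area_weighted_fraction():
    # pitch 1.0 detector grid; leaf edge placed 40% into a pixel
    grid = ImageGrid(nx=16, ny=16, pitch=1.0)
    half_iso = 10.0 / 3.0  # panel half-width then is 5.0
    plan = make_square_field_plan(2 * half_iso)
    c0, c1 = plan.beams[0].control_points
    # move bank A so the panel-plane edge falls at x = +3.9:
    # pixel centred at 3.5 spans [3.0, 4.0] -> 90%? choose 0.4 coverage:
    # edge at 3.4 -> pixel [3.0, 4.0] covered 40%
    c0.bank_a_positions[:] = 3.4 / 1.5
    c1.bank_a_positions[:] = 3.4 / 1.5
    c0.jaw_x2 = c1.jaw_x2 = 10.0
    psi = rasterize_fluence((c0, c1), grid)
    i = np.argmin(np.abs(grid.x - 3.5))
    j = np.argmin(np.abs(grid.y - 0.5))
    assert psi.values[j, i] == pytest.approx(0.4, abs=1e-9)


def test_beam_fluence_partitions_mu(grid16):
    """Summed per-interval fluence of a static beam equals one full
    aperture regardless of up-sampling (partition of unity in MU)."""
    plan = make_square_field_plan(10.0)
    total = beam_fluence(plan.beams[0], grid16)
    up = upsample_control_points(plan, 7)
    total_up = beam_fluence(up.beams[0], grid16)
    np.testing.assert_allclose(total_up.values, total.values, atol=1e-12)
    assert total.values.max() == pytest.approx(1.0)


def test_rasterization_monotone_in_aperture(grid16):
    plan_small = make_square_field_plan(8.0)
    plan_big = make_square_field_plan(12.0)
    p_small = beam_fluence(plan_small.beams[0], grid16)
    p_big = beam_fluence(plan_big.beams[0], grid16)
    assert np.all(p_big.values >= p_small.values - 1e-12)


def test_aperture_outside_grid_warns_and_returns_zero(grid16):
    plan = make_square_field_plan(3.0, center_offset_r=18.0)
    c0, c1 = plan.beams[0].control_points
    with pytest.warns(UserWarning, match="outside"):
        psi = rasterize_fluence((c0, c1), grid16)
    assert not np.any(psi.values)


def test_leaf_transmission_fills_closed_region(grid16):
    plan = make_square_field_plan(10.0)
    c0, c1 = plan.beams[0].control_points
    # widen jaws beyond the MLC opening so a closed-leaf band exists
    for c in (c0, c1):
        c.jaw_x1, c.jaw_x2 = -8.0, 8.0
        c.jaw_y1, c.jaw_y2 = -8.0, 8.0
    psi = rasterize_fluence((c0, c1), grid16, leaf_transmission=0.02)
    X, Y = grid16.mesh()
    under_leaf = (np.abs(X) < 10.0) & (np.abs(Y) > 8.5) & (np.abs(Y) < 11.0)
    assert np.all(np.abs(psi.values[under_leaf] - 0.02) < 1e-9)
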