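"""Commissioning: fTMR derivation, conversion factors, iterative TPS correction."""

import math
from dataclasses import replace

import numpy as np
import pytest

from epidose import (
    BeamGeometry,
    CalibrationConfig,
    MeasurementRecord,
    TPSReferencePoint,
    adjust_fc_with_tps,
    build_fc_table,
    commissioning_reconstructor,
    compute_fc,
    derive_ftmr,
)
from epidose.errors import (
    DegenerateInputError,
    IncompleteGridError,
    PairingError,
)
from epidose.simulate import (
    simulate_commissioning_tps,
    simulate_measurement_set,
    simulate_tmr_table,
)


def _rec(field, t, chamber, cu, role="with-absorber", ssd=None):
    geo = BeamGeometry(field_x=field, field_y=field, ssd_att=ssd, mu=100)
    return MeasurementRecord(geometry=geo, thickness=t, chamber_dose=chamber,
                             cu=cu, role=role)


class TestDeriveFTMR:
    def test_cell_is_with_over_without_ratio(self):
        records = [
            _rec(10, 0, 1.0, 1.0, role="open-reference"),
            _rec(10, 10, 0.5, 0.5, ssd=95.0),
            _rec(10, 20, 0.25, 0.25, ssd=90.0),
        ]
        table = derive_ftmr(records)
        assert table.lookup(10, 10) == pytest.approx(0.5, abs=1e-12)
        assert table.lookup(10, 0) == 1.0

    def test_recovers_exponential_attenuation_at_nodes(self, truth, protocol):
        records = simulate_measurement_set(truth, protocol)
        table = derive_ftmr(records)
        for f in protocol.fields:
            for t in protocol.thicknesses:
                assert table.lookup(f, t) == pytest.approx(
                    math.exp(-truth.mu_eff(f) * t), rel=1e-12
                )

    def test_duplicates_averaged_idempotently(self):
        records = [
            _rec(10, 0, 1.0, 1.0, role="open-reference"),
            _rec(10, 10, 0.5, 0.5, ssd=95.0),
            _rec(10, 10, 0.5, 0.5, ssd=95.0),
        ]
        table = derive_ftmr(records)
        assert table.lookup(10, 10) == pytest.approx(0.5, abs=1e-12)

    def test_inconsistent_duplicates_warn_and_average(self, caplog):
        records = [
            _rec(10, 0, 1.0, 1.0, role="open-reference"),
            _rec(10, 10, 0.50, 0.5, ssd=95.0),
            _rec(10, 10, 0.52, 0.5, ssd=95.0),
        ]
        with caplog.at_level("WARNING"):
            table = derive_ftmr(records)
        assert table.lookup(10, 10) == pytest.approx(0.51, abs=1e-12)
        assert any("spread" in r.message for r in caplog.records)

    def test_missing_open_reference_names_setup(self):
        with pytest.raises(PairingError, match="field 4"):
            derive_ftmr([_rec(4, 10, 0.5, 0.5, ssd=95.0)])


class TestComputeFC:
    def test_hand_evaluated_equation(self, calib):
        # D_TPS=0.8, D_calib=1, CU=0.5, SID=150, SAD=100, fTMR=0.6, TMR=0.9
        tp = TPSReferencePoint(field=10, thickness=15, d_tps=0.8)
        geo = BeamGeometry(sad=100, sid=150, field_x=10, field_y=10)
        fc = compute_fc(tp, calib, cu=0.5, geometry=geo, ftmr=0.6, tmr=0.9)
        assert fc == pytest.approx(0.8 / 0.5 * 2.25 * (0.6 / 0.9), abs=1e-12)
        assert fc == pytest.approx(2.4, abs=1e-12)

    def test_algebraic_identity_gives_unity(self, calib):
        cu, ftmr, tmr = 0.44, 0.62, 0.87
        geo = BeamGeometry(sad=100, sid=150, field_x=10, field_y=10)
        d_tps = calib.d_calib * cu * (100 / 150) ** 2 * tmr / ftmr
        tp = TPSReferencePoint(field=10, thickness=15, d_tps=d_tps)
        assert compute_fc(tp, calib, cu, geo, ftmr, tmr) == pytest.approx(1.0, rel=1e-12)

    def test_zero_cu_guard(self, calib):
        tp = TPSReferencePoint(field=10, thickness=15, d_tps=0.8)
        geo = BeamGeometry(field_x=10, field_y=10)
        with pytest.raises(DegenerateInputError):
            compute_fc(tp, calib, 0.0, geo, 0.6, 0.9)


class TestBuildFCTable:
    def test_full_protocol_grid_populated(self, truth, protocol, calib, tables):
        records = simulate_measurement_set(truth, protocol)
        tps_points = simulate_commissioning_tps(truth, protocol)
        fc = build_fc_table(records, tps_points, calib, tables.ftmr, tables.tmr)
        assert fc.values.shape == (6, 4)
        assert fc.values.size == 24
        # reference cell normalized to 1, raw Gy/CU scale kept separately
        assert fc.lookup(calib.ref_field, 5.0) == pytest.approx(1.0, rel=1e-9)
        assert fc.scale == pytest.approx((150 / 100) ** 2, rel=1e-9)

    def test_single_cell_normalizes_to_one(self, calib, tables):
        records = [
            _rec(10, 0, 1.0, 1.0, role="open-reference"),
            _rec(10, 10, 0.5, 0.37, ssd=95.0),
        ]
        tps = [TPSReferencePoint(field=10, thickness=10, d_tps=0.66)]
        fc = build_fc_table(records, tps, calib, tables.ftmr, tables.tmr)
        assert fc.values.shape == (1, 1)
        assert fc.values[0, 0] == pytest.approx(1.0, rel=1e-12)
        assert fc.scale > 0

    def test_incomplete_grid_lists_missing_cells(self, calib, tables):
        records = [
            _rec(10, 0, 1.0, 1.0, role="open-reference"),
            _rec(10, 10, 0.5, 0.37, ssd=95.0),
        ]
        tps = [
            TPSReferencePoint(field=10, thickness=10, d_tps=0.66),
            TPSReferencePoint(field=4, thickness=10, d_tps=0.60),
        ]
        with pytest.raises(IncompleteGridError, match="field 4"):
            build_fc_table(records, tps, calib, tables.ftmr, tables.tmr)


class TestAdjustFCWithTPS:
    @pytest.fixture
    def setup(self, truth, protocol, calib, tables):
        records = simulate_measurement_set(truth, protocol)
        tps_points = simulate_commissioning_tps(truth, protocol)
        fc = build_fc_table(records, tps_points, calib, tables.ftmr, tables.tmr)
        rec = commissioning_reconstructor(records, calib, tables.ftmr, tables.tmr)
        return fc, tps_points, rec

    def test_fixed_point_returned_unchanged(self, setup):
        fc, tps_points, rec = setup
        adjusted, residuals = adjust_fc_with_tps(fc, tps_points, rec)
        assert residuals.max() < 1e-4
        np.testing.assert_allclose(adjusted.values, fc.values, rtol=1e-9)
        assert adjusted.scale == pytest.approx(fc.scale, rel=1e-9)

    def test_global_tps_offset_absorbed_exactly(self, setup):
        fc, tps_points, rec = setup
        scaled = [replace(p, d_tps=1.02 * p.d_tps) for p in tps_points]
        adjusted, _ = adjust_fc_with_tps(fc, scaled, rec)
        assert adjusted.scale == pytest.approx(1.02 * fc.scale, rel=1e-9)
        np.testing.assert_allclose(adjusted.values, fc.values, rtol=1e-9)

    def test_idempotent_at_convergence(self, setup):
        fc, tps_points, rec = setup
        perturbed = replace(fc, values=fc.values * (1 + 0.05 * np.sin(
            np.arange(fc.values.size).reshape(fc.values.shape))))
        once, _ = adjust_fc_with_tps(perturbed, tps_points, rec)
        twice, _ = adjust_fc_with_tps(once, tps_points, rec)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)
        assert twice.scale == pytest.approx(once.scale, rel=1e-9)

    def test_correction_reduces_max_discrepancy(self, setup):
        fc, tps_points, rec = setup
        rng = np.random.default_rng(7)
        perturbed = replace(
            fc, values=fc.values * rng.uniform(0.95, 1.05, size=fc.values.shape)
        )
        before = max(abs(rec(p, perturbed) - p.d_tps) for p in tps_points)
        adjusted, _ = adjust_fc_with_tps(perturbed, tps_points, rec)
        after = max(abs(rec(p, adjusted) - p.d_tps) for p in tps_points)
        assert after <= before

    def test_zero_tps_dose_guard(self, setup):
        fc, tps_points, rec = setup
        with pytest.raises(DegenerateInputError):
            TPSReferencePoint(field=10, thickness=10, d_tps=0.0)
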