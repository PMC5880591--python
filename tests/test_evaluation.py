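"""Deviation metrics, thresholds/flags, MU sensitivity, auto-POI placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidose import (
    DoseGrid,
    ReconstructedDose,
    auto_poi_sample,
    build_report,
    local_deviation,
    mu_sensitivity,
    plan_summary,
)
from epidose.errors import (
    DegenerateInputError,
    SamplingError,
    UndefinedReferenceError,
)


class TestLocalDeviation:
    def test_equal_doses_give_zero(self):
        assert local_deviation(1.3, 1.3) == 0.0

    def test_underdose_is_negative(self):
        assert local_deviation(0.944, 1.0) == pytest.approx(-5.6, abs=1e-9)

    def test_zero_reference_flagged(self):
        with pytest.raises(UndefinedReferenceError):
            local_deviation(1.0, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(min_value=1e-3, max_value=10),
        b=st.floats(min_value=1e-3, max_value=10),
    )
    def test_antisymmetry_and_zero_iff_equal(self, a, b):
        assert local_deviation(a, b) == -100.0 * (b - a) / b
        if a != b:
            assert local_deviation(a, b) != 0.0


class TestPlanSummary:
    def test_hand_computed_mean_and_sample_sd(self):
        # deviations -1, 0, +1 -> mean 0, sample SD 1
        s = plan_summary([0.99, 1.0, 1.01], [1.0, 1.0, 1.0])
        assert s["mean"] == pytest.approx(0.0, abs=1e-9)
        assert s["sd"] == pytest.approx(1.0, abs=1e-9)

    def test_single_beam_sd_is_zero(self):
        s = plan_summary([1.03], [1.0])
        assert s["mean"] == pytest.approx(3.0, abs=1e-9)
        assert s["sd"] == 0.0

    def test_total_equals_weighted_mean(self):
        recon = [0.5, 1.2]
        tps = [0.6, 1.1]
        s = plan_summary(recon, tps)
        expected = 100 * (sum(recon) - sum(tps)) / sum(tps)
        assert s["total_deviation"] == pytest.approx(expected, rel=1e-12)
        assert s["weighted_mean_deviation"] == s["total_deviation"]

    def test_empty_set_is_error(self):
        with pytest.raises(DegenerateInputError):
            plan_summary([], [])


class TestMUSensitivity:
    def test_identity_cases(self):
        assert mu_sensitivity(0.0, 1.0) == 0.0
        assert mu_sensitivity(0.0, 0.95) == pytest.approx(-5.0, abs=1e-12)

    def test_baseline_compounds_multiplicatively(self):
        # -0.6% baseline with a 5% MU cut -> -5.57, i.e. -5.6 to one decimal
        v = mu_sensitivity(-0.6, 0.95)
        assert v == pytest.approx(-5.57, abs=1e-9)
        assert round(v, 1) == -5.6

    @settings(max_examples=50, deadline=None)
    @given(s=st.floats(min_value=0.1, max_value=2.0))
    def test_pure_scaling_without_baseline(self, s):
        assert mu_sensitivity(0.0, s) == pytest.approx(100 * (s - 1), rel=1e-12)


def _recon(rows):
    """rows: (beam, poi, d_recon, d_tps)"""
    beams = sorted({r[0] for r in rows})
    pois = sorted({r[1] for r in rows})
    rc = ReconstructedDose(beam_ids=beams, poi_labels=pois)
    for b, p, dr, dt in rows:
        rc.dose[(b, p)] = dr
        rc.tps[(b, p)] = dt
    return rc


class TestFlags:
    def test_pass_below_plan_threshold(self):
        rc = _recon([("b1", "iso", 1.049, 1.0)])
        rep = build_report(rc)
        assert rep.poi_summary["iso"]["status"] == "pass"

    def test_fail_above_plan_threshold(self):
        rc = _recon([("b1", "iso", 1.06, 1.0)])
        rep = build_report(rc)
        assert rep.poi_summary["iso"]["status"] == "fail"
        assert not rep.passed

    def test_beam_warning_above_beam_threshold(self):
        rc = _recon([("b1", "iso", 0.5395, 0.5), ("b2", "iso", 0.5, 0.5)])
        rep = build_report(rc)  # b1 deviates 7.9%, below the 8% beam threshold
        flags = {r.beam_id: r.flag for r in rep.rows}
        assert flags["b1"] == "ok"
        rc = _recon([("b1", "iso", 0.5405, 0.5), ("b2", "iso", 0.5, 0.5)])
        flags = {r.beam_id: r.flag for r in build_report(rc).rows}
        assert flags["b1"] == "warn"  # 8.1%, beam contributing 52% of the dose

    def test_low_dose_beam_excluded_from_pass_fail(self):
        # b2 contributes 5% of the TPS dose with a 14% error: excluded, no fail
        rc = _recon([("b1", "iso", 0.95, 0.95), ("b2", "iso", 0.057, 0.05)])
        rep = build_report(rc)
        flags = {r.beam_id: r.flag for r in rep.rows}
        assert flags["b2"] == "low-dose"
        assert rep.poi_summary["iso"]["status"] == "pass"
        assert rep.poi_summary["iso"]["n_beams"] == 1

    def test_removing_low_dose_beam_shrinks_total_error(self):
        rows_all = [("b1", "iso", 1.0, 1.0), ("b2", "iso", 0.06, 0.05)]
        with_b2 = plan_summary([r[2] for r in rows_all], [r[3] for r in rows_all])
        without = plan_summary([1.0], [1.0])
        assert abs(without["total_deviation"]) <= abs(with_b2["total_deviation"])

    def test_thresholds_must_be_positive(self):
        rc = _recon([("b1", "iso", 1.0, 1.0)])
        with pytest.raises(DegenerateInputError):
            build_report(rc, plan_threshold=0.0)


class TestAutoPOISample:
    def make_grid(self):
        v = np.ones((6, 6, 6))
        v[0, 0, 0] = 0.5  # one low-dose voxel
        return DoseGrid(values=v, origin=(-2.5, -2.5, -2.5), spacing=(1, 1, 1))

    def test_points_lie_in_high_dose_region(self):
        grid = self.make_grid()
        pois = auto_poi_sample(grid, n=20, seed=3)
        assert len(pois) == 20
        assert len({p.position for p in pois}) == 20
        for p in pois:
            idx = tuple(int(round((c - o) / s)) for c, o, s in
                        zip(p.position, grid.origin, grid.spacing))
            assert grid.values[idx] >= 0.9 * grid.values.max()

    def test_same_seed_reproduces_points(self):
        grid = self.make_grid()
        a = auto_poi_sample(grid, n=10, seed=11)
        b = auto_poi_sample(grid, n=10, seed=11)
        assert [p.position for p in a] == [p.position for p in b]

    def test_too_few_voxels_suggests_lower_fraction(self):
        grid = DoseGrid(values=np.linspace(0.1, 1.0, 27).reshape(3, 3, 3),
                        origin=(0, 0, 0), spacing=(1, 1, 1))
        with pytest.raises(SamplingError, match="lower high_dose_frac"):
            auto_poi_sample(grid, n=20, high_dose_frac=0.95, seed=1)
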