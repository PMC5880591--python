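"""Reconstruction chain: ray tracing, CU sampling, projection, round trips."""

import numpy as np
import pytest

from epidose import (
    Beam,
    BeamGeometry,
    Plan,
    PointOfInterest,
    PortalImage,
    SlabPhantom,
    cu_to_epid_dose,
    project_to_poi,
    radiological_depth,
    reconstruct_plan,
    sample_cu,
    simulate_cu,
    simulate_tps_dose,
)
from epidose.errors import (
    DegenerateInputError,
    PlanIntegrityError,
    UnsupportedRegionError,
)
from epidose.reconstruction import reconstruct_point
from epidose.simulate import make_plan

ISO = PointOfInterest("iso", (0.0, 0.0, 0.0), role="isocenter")


class TestRadiologicalDepth:
    def test_vertical_beam_midplane_is_half_thickness(self):
        geo = BeamGeometry(field_x=10, field_y=10)
        ph = SlabPhantom(thickness=30, lateral_extent=40)
        assert radiological_depth(geo, ph, ISO) == pytest.approx(15.0, abs=1e-9)

    def test_oblique_path_lengthening(self):
        # 60 deg through a slab that is normal to the vertical beam: 15/cos60 = 30
        geo = BeamGeometry(field_x=10, field_y=10, gantry_angle=60.0)
        ph = SlabPhantom(thickness=30, lateral_extent=200)
        assert radiological_depth(geo, ph, ISO) == pytest.approx(30.0, abs=1e-9)

    def test_point_on_source_side_is_zero(self, caplog):
        geo = BeamGeometry(field_x=10, field_y=10)
        ph = SlabPhantom(thickness=10, lateral_extent=40)
        above = PointOfInterest("above", (0.0, 0.0, 20.0))
        with caplog.at_level("WARNING"):
            assert radiological_depth(geo, ph, above) == 0.0
        assert any("radiological depth is 0" in r.message for r in caplog.records)


class TestSampleCU:
    def test_uniform_image_returns_uniform_value(self):
        geo = BeamGeometry(field_x=10, field_y=10)
        img = PortalImage(pixels=np.full((21, 21), 0.7), spacing_mm=5.0, sid=150,
                          beam_id="b")
        poi = PointOfInterest("p", (1.0, 0.5, 0.0))
        assert sample_cu(img, geo, poi) == pytest.approx(0.7, abs=1e-12)

    def test_scalar_image_is_uniform(self):
        geo = BeamGeometry(field_x=10, field_y=10)
        img = PortalImage.scalar(0.31, sid=150)
        assert sample_cu(img, geo, PointOfInterest("p", (1.5, 0, 0))) == 0.31

    def test_magnification_from_sad_to_sid(self):
        # pixel values encode the crossplane offset in cm: a POI 1.5 cm
        # off-axis at SAD 100 must sample 2.25 cm off-center at SID 150
        geo = BeamGeometry(field_x=10, field_y=10)
        n, spacing = 81, 1.0
        offs = (np.arange(n) - (n - 1) / 2) * spacing / 10.0
        img = PortalImage(pixels=np.tile(offs, (n, 1)) + 10.0, spacing_mm=spacing,
                          sid=150, beam_id="b")
        got = sample_cu(img, geo, PointOfInterest("p", (1.5, 0.0, 0.0)))
        assert got - 10.0 == pytest.approx(2.25, abs=1e-9)


class TestDoseChain:
    def test_cu_to_epid_dose_product(self, calib):
        assert cu_to_epid_dose(0.5, calib, 2.4) == pytest.approx(1.2, abs=1e-12)
        assert cu_to_epid_dose(0.0, calib, 2.4) == 0.0

    def test_cu_to_epid_dose_linearity(self, calib):
        assert cu_to_epid_dose(0.8, calib, 1.7) == pytest.approx(
            2 * cu_to_epid_dose(0.4, calib, 1.7), rel=1e-12
        )

    def test_negative_cu_rejected(self, calib):
        with pytest.raises(DegenerateInputError):
            cu_to_epid_dose(-0.1, calib, 1.0)

    def test_projection_limit_cases(self):
        geo = BeamGeometry(sad=100, sid=150, field_x=10, field_y=10)
        # fTMR = TMR = 1: pure inverse-square from imager to isocenter
        assert project_to_poi(1.0, geo, 1.0, 1.0) == pytest.approx(
            (100 / 150) ** 2, rel=1e-12
        )
        with pytest.raises(DegenerateInputError):
            project_to_poi(1.0, geo, 0.0, 1.0)


class TestRoundTrip:
    @pytest.mark.parametrize("field,thickness", [(10, 20), (4, 5), (15, 30), (2, 10)])
    def test_node_setups_recover_truth_exactly(self, truth, calib, tables,
                                               field, thickness):
        geo = BeamGeometry(field_x=field, field_y=field, mu=100,
                           ssd_att=100 - thickness / 2)
        ph = SlabPhantom(thickness=thickness, lateral_extent=40)
        img = PortalImage.scalar(simulate_cu(truth, geo, ph), sid=geo.sid)
        dose, in_ap = reconstruct_point(geo, ph, img, ISO, tables, calib)
        d_tps = simulate_tps_dose(truth, geo, ph, ISO)
        assert in_ap
        assert abs(dose - d_tps) / d_tps < 1e-10

    def test_off_node_setups_within_half_percent(self, truth, calib, tables):
        for field, thickness in [(12, 15), (6, 25), (10, 17)]:
            geo = BeamGeometry(field_x=field, field_y=field, mu=100,
                               ssd_att=100 - thickness / 2)
            ph = SlabPhantom(thickness=thickness, lateral_extent=40)
            img = PortalImage.scalar(simulate_cu(truth, geo, ph), sid=geo.sid)
            dose, _ = reconstruct_point(geo, ph, img, ISO, tables, calib)
            d_tps = simulate_tps_dose(truth, geo, ph, ISO)
            assert abs(dose - d_tps) / d_tps < 0.005

    def test_sid_change_leaves_reconstruction_invariant(self, truth, calib, tables):
        ph = SlabPhantom(thickness=15, lateral_extent=40)
        doses = []
        for sid in (150.0, 140.0):
            geo = BeamGeometry(field_x=10, field_y=10, mu=100, sid=sid)
            img = PortalImage.scalar(simulate_cu(truth, geo, ph), sid=sid)
            dose, _ = reconstruct_point(geo, ph, img, ISO, tables, calib)
            doses.append(dose)
        assert doses[0] == pytest.approx(doses[1], rel=1e-9)

    def test_buildup_poi_rejected(self, truth, calib, tables):
        geo = BeamGeometry(field_x=10, field_y=10, mu=100)
        ph = SlabPhantom(thickness=15, lateral_extent=40)
        img = PortalImage.scalar(simulate_cu(truth, geo, ph), sid=geo.sid)
        shallow = PointOfInterest("shallow", (0.0, 0.0, 7.0))  # 0.5 cm deep
        with pytest.raises(UnsupportedRegionError):
            reconstruct_point(geo, ph, img, shallow, tables, calib)


class TestReconstructPlan:
    def test_ap_pa_round_trip_and_totals(self, truth, calib, tables):
        fix = make_plan("ap_pa", truth=truth)
        recon = reconstruct_plan(fix.plan, fix.images, fix.pois, tables, calib,
                                 tps=fix.tps)
        for label in recon.poi_labels:
            total = recon.total(label)
            ref = recon.tps_total(label)
            assert abs(total - ref) / ref < 1e-4
            assert total == pytest.approx(
                sum(recon.dose[(b, label)] for b in recon.beam_ids), rel=1e-12
            )

    def test_mu_doubling_doubles_all_doses(self, truth, calib, tables):
        fix1 = make_plan("single_field", truth=truth, scalar_images=True)
        fix2 = make_plan("single_field", truth=truth, mu=200.0, scalar_images=True)
        r1 = reconstruct_plan(fix1.plan, fix1.images, fix1.pois, tables, calib)
        r2 = reconstruct_plan(fix2.plan, fix2.images, fix2.pois, tables, calib)
        for key in r1.dose:
            assert r2.dose[key] == pytest.approx(2 * r1.dose[key], rel=1e-12)

    def test_single_beam_total_equals_beam_dose(self, truth, calib, tables):
        fix = make_plan("single_field", truth=truth, scalar_images=True)
        recon = reconstruct_plan(fix.plan, fix.images, fix.pois, tables, calib)
        b = recon.beam_ids[0]
        for label in recon.poi_labels:
            assert recon.total(label) == recon.dose[(b, label)]

    def test_missing_image_is_plan_integrity_error(self, truth, calib, tables):
        fix = make_plan("ap_pa", truth=truth, scalar_images=True)
        images = dict(fix.images)
        images.pop(fix.plan.beams[0].beam_id)
        with pytest.raises(PlanIntegrityError, match=fix.plan.beams[0].beam_id):
            reconstruct_plan(fix.plan, images, fix.pois, tables, calib)

    def test_phantom_required(self, tables, calib):
        plan = Plan(label="p", beams=[Beam("b1", BeamGeometry(field_x=10, field_y=10))])
        with pytest.raises(PlanIntegrityError):
            reconstruct_plan(plan, {"b1": PortalImage.scalar(1.0)}, [ISO],
                             tables, calib)
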