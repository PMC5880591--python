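"""Virtual linac: a synthetic truth model for the whole transit-dosimetry chain.

The truth model is a deliberately simple 6 MV-like beam: exponential
attenuation with an effective coefficient that softens logarithmically with
field size (more phantom scatter reaches the imager for larger fields), a
logarithmic output factor, inverse-square divergence, and optional
multiplicative Gaussian noise (default 0, so all fixtures are exact and the
commission -> reconstruct round trip closes to machine precision).

    CU      = (MU/100) * OF(f) * exp(-mu_eff(f) * path) * (ref_sid/SID)^2
    D(poi)  = (MU/100) * D_calib * OF(f) * TMR(f, depth) * (ref_sad/r)^2
    TMR(f, d)  = exp(-mu_eff(f) * (d - d_max))
    fTMR(f, t) = exp(-mu_eff(f) * t)
    mu_eff(f)  = mu0 * (1 - k * ln(f/10));   OF(f) = 1 + s * ln(f/10)

Everything other modules consume — commissioning measurement records,
TPS reference points, portal images, plan fixtures, dose grids — is
generated from these closed forms, so each pipeline stage has an exact
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .commissioning import MeasurementRecord, TPSReferencePoint
from .errors import InvalidGeometryError, TemplateError, UnsupportedRegionError
from .reconstruction import (
    Beam,
    DoseGrid,
    Plan,
    PointOfInterest,
    PortalImage,
    SlabPhantom,
    _ray_box,
    beam_basis,
    source_position,
    trace_point,
)
from .tables import BeamGeometry, CalibrationConfig, TMRTable

DEFAULT_TMR_DEPTHS = (1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0,
                      15.0, 18.0, 21.0, 25.0, 30.0, 35.0)


@dataclass(frozen=True)
class TruthModel:
    """Parameters of the synthetic beam/imager physics.

    mu0: effective linear attenuation coefficient in water, 1/cm.
    field_scatter: dimensionless softening of mu_eff per ln(field/10).
    of_log_slope: output-factor slope per ln(field/10).
    noise: relative SD of multiplicative Gaussian noise on CU and chamber
        doses (0 = exact fixtures; reproducible under a seeded rng).
    """

    mu0: float = 0.05
    field_scatter: float = 0.03
    of_log_slope: float = 0.08
    noise: float = 0.0
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)

    def __post_init__(self):
        if self.mu0 <= 0:
            raise InvalidGeometryError("mu0 must be positive")
        if self.noise < 0:
            raise InvalidGeometryError("noise must be >= 0")

    def mu_eff(self, eq_field: float) -> float:
        return self.mu0 * (1.0 - self.field_scatter * math.log(eq_field / 10.0))

    def output_factor(self, eq_field: float) -> float:
        return 1.0 + self.of_log_slope * math.log(eq_field / 10.0)

    def ftmr(self, eq_field: float, thickness: float) -> float:
        return math.exp(-self.mu_eff(eq_field) * thickness)

    def tmr(self, eq_field: float, depth: float) -> float:
        return math.exp(-self.mu_eff(eq_field) * (depth - self.calibration.d_max))


def _noise_factor(truth: TruthModel, rng: np.random.Generator | None, shape=None):
    if truth.noise == 0:
        return 1.0 if shape is None else np.ones(shape)
    if rng is None:
        raise InvalidGeometryError("noise > 0 requires a seeded rng")
    return rng.normal(1.0, truth.noise, size=shape)


# ---------------------------------------------------------------------------
# elementary signals
# ---------------------------------------------------------------------------


def simulate_cu(truth: TruthModel, geometry: BeamGeometry, phantom: SlabPhantom,
                *, image: bool = False, spacing_mm: float = 2.0,
                margin_cm: float = 2.0,
                rng: np.random.Generator | None = None) -> float | PortalImage:
    """Integrated CU for one delivery: scalar central value or a 2-D image.

    Scalar: the reading on the central axis.  Image: per-pixel ray tracing
    through the phantom with the jaw aperture projected to the imager plane
    (zero transmission outside the jaws, hard edge).
    """
    calib = truth.calibration
    eq = geometry.eq_field
    base = (geometry.mu / 100.0) * truth.output_factor(eq) \
        * (calib.ref_sid / geometry.sid) ** 2
    mu_eff = truth.mu_eff(eq)
    src = source_position(geometry)
    center = np.asarray(phantom.center, float)
    half = phantom.half_sizes()
    if not image:
        # path along the central axis (ray through the isocenter)
        lam_in, lam_out, _, miss = _ray_box(src, np.zeros((1, 3)), center, half)
        path = 0.0 if miss[0] else float(lam_out[0] - lam_in[0])
        cu = base * math.exp(-mu_eff * path) * float(np.ravel(_noise_factor(truth, rng))[0])
        return cu

    mag = geometry.sid / geometry.sad
    half_x = geometry.field_x / 2.0 * mag + margin_cm
    half_y = geometry.field_y / 2.0 * mag + margin_cm
    nx = 2 * int(round(half_x * 10.0 / spacing_mm)) + 1
    ny = 2 * int(round(half_y * 10.0 / spacing_mm)) + 1
    bx = (np.arange(nx) - (nx - 1) / 2.0) * spacing_mm / 10.0  # cm crossplane
    by = (np.arange(ny) - (ny - 1) / 2.0) * spacing_mm / 10.0  # cm inplane
    u, v, w = beam_basis(geometry)
    BX, BY = np.meshgrid(bx, by)  # (ny, nx): rows inplane, cols crossplane
    pts = (src[None, None, :] + geometry.sid * u[None, None, :]
           + BX[..., None] * v[None, None, :] + BY[..., None] * w[None, None, :])
    lam_in, lam_out, _, miss = _ray_box(src, pts.reshape(-1, 3), center, half)
    path = np.where(miss, 0.0, lam_out - lam_in).reshape(ny, nx)
    in_ap = (
        (np.abs(BX) / mag <= geometry.field_x / 2.0 + 1e-9)
        & (np.abs(BY) / mag <= geometry.field_y / 2.0 + 1e-9)
    )
    pixels = base * np.exp(-mu_eff * path) * in_ap
    pixels = pixels * _noise_factor(truth, rng, pixels.shape)
    return PortalImage(pixels=np.clip(pixels, 0.0, None), spacing_mm=spacing_mm,
                       sid=geometry.sid, beam_id="beam")


def simulate_tps_dose(truth: TruthModel, geometry: BeamGeometry,
                      phantom: SlabPhantom, poi: PointOfInterest) -> float:
    """Planning-system-style dose at a POI (deterministic, noise-free).

    Zero outside the jaw aperture; an in-field point shallower than D_max is
    rejected (build-up region).
    """
    tr = trace_point(geometry, phantom, poi.position)
    if not tr.in_aperture:
        return 0.0
    calib = truth.calibration
    if tr.depth < calib.d_max:
        raise UnsupportedRegionError(
            f"POI '{poi.label}' at depth {tr.depth:.2f} cm is in the build-up region"
        )
    eq = geometry.eq_field
    return (
        (geometry.mu / 100.0) * calib.d_calib * truth.output_factor(eq)
        * truth.tmr(eq, tr.depth) * (calib.ref_sad / tr.source_distance) ** 2
    )


def simulate_chamber_dose(truth: TruthModel, geometry: BeamGeometry,
                          thickness: float,
                          rng: np.random.Generator | None = None) -> float:
    """Ion-chamber dose at D_max in virtual water at the imager plane (Gy)."""
    calib = truth.calibration
    eq = geometry.eq_field
    return (
        (geometry.mu / 100.0) * calib.d_calib * truth.output_factor(eq)
        * math.exp(-truth.mu_eff(eq) * thickness)
        * (calib.ref_sad / geometry.sid) ** 2
        * float(np.ravel(_noise_factor(truth, rng))[0])
    )


# ---------------------------------------------------------------------------
# commissioning fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommissioningProtocol:
    """Grid of commissioning setups (fields x thicknesses x SSD_att steps)."""

    fields: Sequence[float] = (2.0, 4.0, 8.0, 10.0, 15.0, 20.0)
    thicknesses: Sequence[float] = (5.0, 10.0, 20.0, 30.0)
    n_ssd_steps: int = 1   # extra SSD_att positions, stepped by t/2 toward the source
    sad: float = 100.0
    sid: float = 150.0
    mu: float = 100.0

    def __post_init__(self):
        if not self.fields or not self.thicknesses:
            raise InvalidGeometryError("protocol needs at least one field and thickness")
        if self.n_ssd_steps < 1:
            raise InvalidGeometryError("n_ssd_steps must be >= 1")

    def ssd_att_values(self, thickness: float) -> list[float]:
        # phantom centered at isocenter, then stepped toward the source by t/2
        base = self.sad - thickness / 2.0
        return [base - k * thickness / 2.0 for k in range(self.n_ssd_steps)]


def simulate_measurement_set(truth: TruthModel,
                             protocol: CommissioningProtocol | None = None,
                             seed: int | None = None) -> list[MeasurementRecord]:
    """One measurement record per protocol setup plus an open-field reference
    per field size; deterministic under a given seed."""
    protocol = protocol or CommissioningProtocol()
    rng = np.random.default_rng(seed) if truth.noise > 0 else None
    records = []
    for f in protocol.fields:
        open_geo = BeamGeometry(sad=protocol.sad, sid=protocol.sid, ssd_att=None,
                                field_x=f, field_y=f, mu=protocol.mu)
        records.append(MeasurementRecord(
            geometry=open_geo, thickness=0.0,
            chamber_dose=simulate_chamber_dose(truth, open_geo, 0.0, rng),
            cu=simulate_cu(truth, open_geo,
                           SlabPhantom(thickness=0.0, lateral_extent=40.0), rng=rng),
            role="open-reference",
        ))
        for t in protocol.thicknesses:
            for ssd in protocol.ssd_att_values(t):
                geo = BeamGeometry(sad=protocol.sad, sid=protocol.sid, ssd_att=ssd,
                                   field_x=f, field_y=f, mu=protocol.mu)
                phantom = SlabPhantom.for_commissioning(t, ssd, protocol.sad,
                                                        lateral_extent=40.0)
                records.append(MeasurementRecord(
                    geometry=geo, thickness=t,
                    chamber_dose=simulate_chamber_dose(truth, geo, t, rng),
                    cu=simulate_cu(truth, geo, phantom, rng=rng),
                    role="with-absorber",
                ))
    return records


def simulate_commissioning_tps(truth: TruthModel,
                               protocol: CommissioningProtocol | None = None
                               ) -> list[TPSReferencePoint]:
    """TPS isocenter doses for the (field, thickness) commissioning grid
    (phantom centered at the isocenter, so the isocenter depth is t/2)."""
    protocol = protocol or CommissioningProtocol()
    pts = []
    iso = PointOfInterest("isocenter", (0.0, 0.0, 0.0), role="isocenter")
    for f in protocol.fields:
        for t in protocol.thicknesses:
            geo = BeamGeometry(sad=protocol.sad, sid=protocol.sid,
                               ssd_att=protocol.sad - t / 2.0,
                               field_x=f, field_y=f, mu=protocol.mu)
            phantom = SlabPhantom(thickness=t, lateral_extent=40.0)
            pts.append(TPSReferencePoint(
                field=f, thickness=t,
                d_tps=simulate_tps_dose(truth, geo, phantom, iso),
                depth=t / 2.0,
            ))
    return pts


def simulate_tmr_table(truth: TruthModel,
                       fields: Sequence[float] | None = None,
                       depths: Sequence[float] | None = None) -> TMRTable:
    """TMR table from TPS-style depth-dose ratios (standard beam data)."""
    fields = tuple(fields) if fields is not None else CommissioningProtocol().fields
    depths = tuple(depths) if depths is not None else DEFAULT_TMR_DEPTHS
    values = np.array([[truth.tmr(f, d) for d in depths] for f in fields])
    return TMRTable(fields=np.asarray(fields, float),
                    depths=np.asarray(depths, float),
                    values=values, d_max=truth.calibration.d_max)


def commission_from_truth(truth: TruthModel,
                          protocol: CommissioningProtocol | None = None,
                          seed: int | None = None):
    """Full commissioning chain on simulated measurements.

    Returns ``(TableSet, residuals)`` with the conversion factors already run
    through the iterative TPS correction.
    """
    from .commissioning import (
        adjust_fc_with_tps,
        build_fc_table,
        commissioning_reconstructor,
        derive_ftmr,
    )
    from .tables import TableSet

    protocol = protocol or CommissioningProtocol()
    records = simulate_measurement_set(truth, protocol, seed=seed)
    tps_points = simulate_commissioning_tps(truth, protocol)
    ftmr = derive_ftmr(records)
    tmr = simulate_tmr_table(truth, fields=protocol.fields)
    fc = build_fc_table(records, tps_points, truth.calibration, ftmr, tmr)
    reconstructor = commissioning_reconstructor(records, truth.calibration, ftmr, tmr)
    fc, residuals = adjust_fc_with_tps(fc, tps_points, reconstructor)
    return TableSet(ftmr=ftmr, tmr=tmr, fc=fc), residuals


# ---------------------------------------------------------------------------
# plan templates
# ---------------------------------------------------------------------------


def _split_mu(total: float, n: int) -> list[float]:
    base = total / n
    mus = [round(base)] * n
    mus[0] += total - sum(mus)
    return [float(m) for m in mus]


# (gantry angles, field_x, field_y, total MU, phantom thickness)
_TEMPLATES: dict[str, dict] = {
    "single_field": dict(gantry=(0.0,), fx=10.0, fy=10.0, total_mu=100.0, t=15.0),
    "ap_pa": dict(gantry=(0.0, 180.0), fx=10.0, fy=10.0, total_mu=470.0, t=15.0),
    "bands": dict(gantry=(0.0, 180.0), fx=20.0, fy=10.0, total_mu=200.0, t=15.0),
    "multitarget_like": dict(gantry=(0.0, 51.0, 103.0, 154.0, 206.0, 257.0, 309.0),
                             fx=10.0, fy=10.0, total_mu=1043.0, t=15.0),
    "prostate_like": dict(gantry=(0.0, 50.0, 100.0, 155.0, 205.0, 260.0, 310.0),
                          fx=8.0, fy=8.0, total_mu=1452.0, t=15.0),
    "hn_like": dict(gantry=(0.0, 40.0, 80.0, 120.0, 160.0, 200.0, 240.0, 280.0, 320.0),
                    fx=10.0, fy=10.0, total_mu=2577.0, t=15.0),
    "cshape_like": dict(gantry=(0.0, 40.0, 80.0, 120.0, 160.0, 200.0, 240.0, 280.0, 320.0),
                        fx=10.0, fy=10.0, total_mu=1846.0, t=15.0),
}

_DEFAULT_POIS = (
    PointOfInterest("isocenter", (0.0, 0.0, 0.0), role="isocenter"),
    PointOfInterest("left_1p5cm", (1.5, 0.0, 0.0), role="offset"),
    PointOfInterest("post_2cm", (0.0, 0.0, -2.0), role="offset"),
)


@dataclass
class PlanFixture:
    """A synthetic plan together with its delivery and reference data."""

    template: str
    plan: Plan
    phantom: SlabPhantom
    pois: list[PointOfInterest]
    images: dict               # beam_id -> PortalImage (delivered, incl. mu_scale)
    tps: dict                  # (beam_id, poi label) -> Gy (planned)
    delivered_mu: dict         # beam_id -> MU actually delivered
    mu_scale: float
    truth: TruthModel


def make_plan(template: str, *, mu_scale: float = 1.0,
              truth: TruthModel | None = None, seed: int | None = None,
              field_size: float | None = None, thickness: float | None = None,
              mu: float | None = None, image_spacing_mm: float = 2.0,
              scalar_images: bool = False,
              pois: Iterable[PointOfInterest] | None = None) -> PlanFixture:
    """Build a named plan template plus simulated delivery fixtures.

    Templates mirror the standard multi-beam/IMRT test-suite structures
    (AP/PA pair, bands pair, 7- and 9-beam arrangements) in beam count and
    total MU.  ``mu_scale`` scales the *delivered* MU only (the plan keeps
    its nominal values), emulating a delivery-error sensitivity test.
    ``field_size``/``thickness``/``mu`` override the single_field template.
    """
    if template not in _TEMPLATES:
        raise TemplateError(
            f"unknown template '{template}'; choose from {sorted(_TEMPLATES)}"
        )
    truth = truth or TruthModel()
    cfg = dict(_TEMPLATES[template])
    if template == "single_field":
        if field_size is not None:
            cfg["fx"] = cfg["fy"] = field_size
        if thickness is not None:
            cfg["t"] = thickness
        if mu is not None:
            cfg["total_mu"] = mu
    mus = _split_mu(cfg["total_mu"], len(cfg["gantry"]))
    phantom = SlabPhantom(thickness=cfg["t"], lateral_extent=30.0)
    beams = []
    for k, (g, m) in enumerate(zip(cfg["gantry"], mus), start=1):
        beams.append(Beam(
            beam_id=f"b{k:02d}_g{int(round(g)):03d}",
            geometry=BeamGeometry(sad=100.0, sid=150.0, ssd_att=None,
                                  gantry_angle=g, field_x=cfg["fx"],
                                  field_y=cfg["fy"], mu=m),
        ))
    plan = Plan(label=template, beams=beams, phantom=phantom)
    poi_list = list(pois) if pois is not None else list(_DEFAULT_POIS)

    rng = np.random.default_rng(seed) if truth.noise > 0 else None
    images, tps, delivered = {}, {}, {}
    for beam in beams:
        geo = beam.geometry
        delivered_geo = replace(geo, mu=geo.mu * mu_scale)
        delivered[beam.beam_id] = delivered_geo.mu
        if scalar_images:
            cu = simulate_cu(truth, delivered_geo, phantom, rng=rng)
            img = PortalImage.scalar(cu, sid=geo.sid, beam_id=beam.beam_id)
        else:
            img = simulate_cu(truth, delivered_geo, phantom, image=True,
                              spacing_mm=image_spacing_mm, rng=rng)
            img.beam_id = beam.beam_id
        images[beam.beam_id] = img
        for poi in poi_list:
            tps[(beam.beam_id, poi.label)] = simulate_tps_dose(truth, geo, phantom, poi)
    return PlanFixture(template=template, plan=plan, phantom=phantom,
                       pois=poi_list, images=images, tps=tps,
                       delivered_mu=delivered, mu_scale=mu_scale, truth=truth)


def simulate_dose_grid(truth: TruthModel, plan: Plan, phantom: SlabPhantom,
                       *, half_extent: float = 2.5, spacing: float = 1.0) -> DoseGrid:
    """Summed TPS-style dose on a regular grid around the isocenter.

    The grid is kept well inside the phantom and inside every beam's
    aperture margin of validity; voxels outside a beam's jaws simply receive
    no contribution from it.
    """
    n = 2 * int(round(half_extent / spacing)) + 1
    axis = (np.arange(n) - (n - 1) / 2.0) * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    total = np.zeros(pts.shape[0])
    calib = truth.calibration
    center = np.asarray(phantom.center, float)
    half = phantom.half_sizes()
    for beam in plan.beams:
        geo = beam.geometry
        src = source_position(geo)
        u, v, w = beam_basis(geo)
        d = pts - src
        dist = np.linalg.norm(d, axis=1)
        a = d @ u
        bx = d @ v
        cy = d @ w
        lam_in, lam_out, _, miss = _ray_box(src, pts, center, half)
        depth = np.clip(dist - lam_in, 0.0, lam_out - lam_in)
        scale = geo.sad / a
        in_ap = ((np.abs(bx * scale) <= geo.field_x / 2.0 + 1e-9)
                 & (np.abs(cy * scale) <= geo.field_y / 2.0 + 1e-9)
                 & ~miss & (depth >= calib.d_max))
        eq = geo.eq_field
        contrib = ((geo.mu / 100.0) * calib.d_calib * truth.output_factor(eq)
                   * np.exp(-truth.mu_eff(eq) * (depth - calib.d_max))
                   * (calib.ref_sad / dist) ** 2)
        total += np.where(in_ap, contrib, 0.0)
    return DoseGrid(values=total.reshape(n, n, n),
                    origin=(float(axis[0]),) * 3,
                    spacing=(spacing,) * 3)
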