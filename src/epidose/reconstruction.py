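"""Point-dose reconstruction from integrated portal images.

The chain per beam and point of interest (POI) is::

    CU at the POI's imager projection          (sample_cu)
      -> dose-to-water at imager level, D_max  (cu_to_epid_dose)
      -> dose at the POI inside the phantom    (project_to_poi)

The projection step is the algebraic inverse of the conversion-factor
commissioning equation

    FC = D_TPS / (D_calib * CU) * (SID/SAD)^2 * fTMR / TMR

generalized to a POI at source distance ``r`` and to deliveries whose SID
differs from the commissioning SID ``SID_cal``::

    D = D_epid * (SAD/SID_cal)^2 * (SID/SID_cal)^2 * (SAD/r)^2 * TMR / fTMR

which reduces to the printed inverse at the isocenter (r = SAD) for
deliveries at the commissioning SID.  Coordinates: IEC-style fixed frame with
the isocenter at the origin, x lateral, y along the couch, z vertical (up);
gantry 0 points the beam straight down.  Distances in cm, doses in Gy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    DegenerateInputError,
    InvalidGeometryError,
    OffImagerError,
    PlanIntegrityError,
    UnsupportedRegionError,
)
from .tables import BeamGeometry, CalibrationConfig, TableSet, equivalent_square

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phantom and beam-frame geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlabPhantom:
    """Axis-aligned solid-water slab, centered at ``center`` (cm).

    ``orientation='flat'`` puts the thickness along z (slab lying on the
    couch); ``'side'`` puts it along x (slab standing on its side, as used
    for lateral beams to keep the couch out of the beam).
    """

    thickness: float
    lateral_extent: float = 30.0
    orientation: str = "flat"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.thickness < 0:
            raise InvalidGeometryError("slab thickness must be >= 0")
        if self.lateral_extent <= 0:
            raise InvalidGeometryError("lateral extent must be positive")
        if self.orientation not in ("flat", "side"):
            raise InvalidGeometryError("orientation must be 'flat' or 'side'")

    @classmethod
    def for_commissioning(
        cls, thickness: float, ssd_att: float, sad: float = 100.0, **kw
    ) -> "SlabPhantom":
        """Flat slab whose top surface sits ``ssd_att`` below the source."""
        cz = sad - ssd_att - thickness / 2.0
        return cls(thickness=thickness, center=(0.0, 0.0, cz), **kw)

    def half_sizes(self) -> np.ndarray:
        e = self.lateral_extent / 2.0
        t = self.thickness / 2.0
        if self.orientation == "flat":
            return np.array([e, e, t])
        return np.array([t, e, e])

    def to_dict(self) -> dict:
        return {
            "thickness": self.thickness,
            "lateral_extent": self.lateral_extent,
            "orientation": self.orientation,
            "center": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlabPhantom":
        return cls(
            thickness=float(d["thickness"]),
            lateral_extent=float(d.get("lateral_extent", 30.0)),
            orientation=str(d.get("orientation", "flat")),
            center=tuple(float(c) for c in d.get("center", (0.0, 0.0, 0.0))),
        )


def source_position(geometry: BeamGeometry) -> np.ndarray:
    th = np.deg2rad(geometry.gantry_angle)
    return geometry.sad * np.array([np.sin(th), 0.0, np.cos(th)])


def beam_basis(geometry: BeamGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, v, w): beam axis direction, crossplane (jaw X) and inplane (jaw Y)."""
    th = np.deg2rad(geometry.gantry_angle)
    u = -np.array([np.sin(th), 0.0, np.cos(th)])
    v = np.array([np.cos(th), 0.0, -np.sin(th)])
    w = np.array([0.0, 1.0, 0.0])
    return u, v, w


def _ray_box(src: np.ndarray, targets: np.ndarray, center: np.ndarray,
             half: np.ndarray):
    """Vectorized ray/box intersection along rays src -> targets.

    Returns ``(lam_in, lam_out, dist, miss)`` where lam are distances from
    the source along each (unit-direction) ray, clipped to the forward
    half-line, and ``dist`` is the source-to-target distance.
    """
    targets = np.asarray(targets, dtype=float)
    d = targets - src
    dist = np.linalg.norm(d, axis=-1)
    e = d / dist[..., None]
    lam_in = np.zeros(dist.shape)
    lam_out = np.full(dist.shape, np.inf)
    miss = np.zeros(dist.shape, dtype=bool)
    for i in range(3):
        ei = e[..., i]
        lo = center[i] - half[i]
        hi = center[i] + half[i]
        parallel = np.abs(ei) < 1e-12
        miss |= parallel & ~((src[i] >= lo) & (src[i] <= hi))
        with np.errstate(divide="ignore", invalid="ignore"):
            l1 = (lo - src[i]) / ei
            l2 = (hi - src[i]) / ei
        a = np.minimum(l1, l2)
        b = np.maximum(l1, l2)
        lam_in = np.where(parallel, lam_in, np.maximum(lam_in, a))
        lam_out = np.where(parallel, lam_out, np.minimum(lam_out, b))
    miss |= lam_out <= lam_in
    lam_in = np.where(miss, 0.0, lam_in)
    lam_out = np.where(miss, 0.0, lam_out)
    return lam_in, lam_out, dist, miss


@dataclass(frozen=True)
class RayTrace:
    """Per-(beam, point) geometry derived by :func:`trace_point`."""

    depth: float            # water-equivalent path from slab entry to point, cm
    path: float             # full slab crossing along the ray, cm
    source_distance: float  # source-to-point distance, cm
    in_aperture: bool       # does the point's ray pass the jaw opening?
    offset_x: float         # crossplane transverse offset at the point, cm
    offset_y: float         # inplane transverse offset at the point, cm
    axial: float            # distance along the beam axis, cm
    missed: bool            # ray does not intersect the phantom


def trace_point(geometry: BeamGeometry, phantom: SlabPhantom,
                position) -> RayTrace:
    p = np.asarray(position, dtype=float)
    src = source_position(geometry)
    u, v, w = beam_basis(geometry)
    d = p - src
    a = float(d @ u)
    if a <= 0:
        raise InvalidGeometryError("point lies behind the source")
    b = float(d @ v)
    c = float(d @ w)
    lam_in, lam_out, dist, miss = _ray_box(
        src, p[None, :], np.asarray(phantom.center, float), phantom.half_sizes()
    )
    lam_in, lam_out, dist, miss = (
        float(lam_in[0]), float(lam_out[0]), float(dist[0]), bool(miss[0]),
    )
    if miss:
        depth = path = 0.0
    else:
        path = max(lam_out - lam_in, 0.0)
        depth = float(np.clip(dist - lam_in, 0.0, path))
    scale = geometry.sad / a
    in_ap = (
        abs(b * scale) <= geometry.field_x / 2.0 + 1e-9
        and abs(c * scale) <= geometry.field_y / 2.0 + 1e-9
    )
    return RayTrace(depth, path, dist, in_ap, b, c, a, miss)


def radiological_depth(geometry: BeamGeometry, phantom: SlabPhantom,
                       poi: "PointOfInterest") -> float:
    """Water-equivalent depth of the POI along the ray from the source.

    0 with a logged warning when the ray misses the phantom or the point sits
    on the source side of it (point effectively in air).
    """
    tr = trace_point(geometry, phantom, poi.position)
    if tr.missed or tr.depth == 0.0:
        logger.warning(
            "ray through POI '%s' does not pass the phantom before the point; "
            "radiological depth is 0", poi.label,
        )
    return tr.depth


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointOfInterest:
    """Named evaluation point in the fixed (phantom) frame, cm."""

    label: str
    position: tuple[float, float, float]
    role: str = "offset"  # isocenter | offset | target | OAR

    def to_dict(self) -> dict:
        return {"label": self.label, "position": list(self.position), "role": self.role}

    @classmethod
    def from_dict(cls, d: dict) -> "PointOfInterest":
        return cls(
            label=str(d["label"]),
            position=tuple(float(c) for c in d["position"]),
            role=str(d.get("role", "offset")),
        )


@dataclass
class PortalImage:
    """Integrated calibrated-unit (CU) image for one beam.

    ``pixels`` is a 2-D array in the imager plane (rows = inplane/jaw-Y,
    columns = crossplane/jaw-X, centered on the beam axis).  A 1x1 array is a
    scalar central CU reading, treated as spatially uniform.
    """

    pixels: np.ndarray
    spacing_mm: float
    sid: float
    beam_id: str

    def __post_init__(self):
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        if self.spacing_mm <= 0:
            raise InvalidGeometryError("pixel spacing must be positive")
        if np.any(self.pixels < 0):
            raise InvalidGeometryError("CU values must be non-negative")

    @classmethod
    def scalar(cls, cu: float, sid: float = 150.0, beam_id: str = "beam") -> "PortalImage":
        return cls(pixels=np.array([[cu]]), spacing_mm=1.0, sid=sid, beam_id=beam_id)

    @property
    def is_scalar(self) -> bool:
        return self.pixels.size == 1

    def to_dict(self) -> dict:
        d = {"schema": "portal-image/1", "beam_id": self.beam_id,
             "sid": self.sid, "spacing_mm": self.spacing_mm}
        if self.is_scalar:
            d["cu"] = float(self.pixels.ravel()[0])
        else:
            d["pixels"] = self.pixels.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PortalImage":
        px = np.array([[float(d["cu"])]]) if "cu" in d else np.asarray(d["pixels"], float)
        return cls(pixels=px, spacing_mm=float(d.get("spacing_mm", 1.0)),
                   sid=float(d["sid"]), beam_id=str(d["beam_id"]))


@dataclass(frozen=True)
class Beam:
    beam_id: str
    geometry: BeamGeometry

    def to_dict(self) -> dict:
        return {"beam_id": self.beam_id, **self.geometry.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "Beam":
        return cls(beam_id=str(d["beam_id"]), geometry=BeamGeometry.from_dict(d))


@dataclass
class Plan:
    """A treatment plan: named beams plus (optionally) the phantom it targets."""

    label: str
    beams: list[Beam]
    phantom: SlabPhantom | None = None

    def to_dict(self) -> dict:
        d = {"schema": "plan/1", "label": self.label,
             "beams": [b.to_dict() for b in self.beams]}
        if self.phantom is not None:
            d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Plan":
        ph = d.get("phantom")
        return cls(
            label=str(d.get("label", "plan")),
            beams=[Beam.from_dict(b) for b in d["beams"]],
            phantom=None if ph is None else SlabPhantom.from_dict(ph),
        )


@dataclass
class DoseGrid:
    """Regular 3-D dose grid; ``values[ix, iy, iz]``, origin/spacing in cm."""

    values: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidGeometryError("dose grid must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise InvalidGeometryError("grid spacing must be positive")

    def voxel_position(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def to_dict(self) -> dict:
        return {
            "schema": "dose-grid/1",
            "shape": list(self.values.shape),
            "origin": list(self.origin),
            "spacing": list(self.spacing),
            "values": self.values.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoseGrid":
        shape = tuple(int(n) for n in d["shape"])
        return cls(
            values=np.asarray(d["values"], float).reshape(shape),
            origin=tuple(float(c) for c in d["origin"]),
            spacing=tuple(float(c) for c in d["spacing"]),
        )


@dataclass
class ReconstructedDose:
    """Per-beam reconstructed doses at each POI, with optional TPS references."""

    beam_ids: list[str]
    poi_labels: list[str]
    dose: dict = field(default_factory=dict)       # (beam_id, label) -> Gy
    tps: dict = field(default_factory=dict)        # (beam_id, label) -> Gy
    low_confidence: set = field(default_factory=set)

    def total(self, label: str) -> float:
        return sum(self.dose[(b, label)] for b in self.beam_ids)

    def tps_total(self, label: str) -> float:
        return sum(self.tps[(b, label)] for b in self.beam_ids)

    def to_dict(self) -> dict:
        rows = []
        for b in self.beam_ids:
            for p in self.poi_labels:
                rows.append({
                    "beam_id": b,
                    "poi": p,
                    "dose": self.dose[(b, p)],
                    "tps": self.tps.get((b, p)),
                    "low_confidence": (b, p) in self.low_confidence,
                })
        return {"schema": "recon/1", "beam_ids": self.beam_ids,
                "poi_labels": self.poi_labels, "rows": rows}

    @classmethod
    def from_dict(cls, d: dict) -> "ReconstructedDose":
        out = cls(beam_ids=list(d["beam_ids"]), poi_labels=list(d["poi_labels"]))
        for r in d["rows"]:
            key = (str(r["beam_id"]), str(r["poi"]))
            out.dose[key] = float(r["dose"])
            if r.get("tps") is not None:
                out.tps[key] = float(r["tps"])
            if r.get("low_confidence"):
                out.low_confidence.add(key)
        return out


# ---------------------------------------------------------------------------
# the reconstruction chain
# ---------------------------------------------------------------------------


def sample_cu(image: PortalImage, geometry: BeamGeometry, poi: PointOfInterest,
              phantom: SlabPhantom | None = None) -> float:
    """Bilinear-sampled CU at the POI's central projection on the imager.

    The imager-plane offset is the POI's transverse offset magnified by
    ``sid / (source-to-poi axial distance)``.  Scalar (1x1) images are
    uniform and return their single value.
    """
    src = source_position(geometry)
    u, v, w = beam_basis(geometry)
    d = np.asarray(poi.position, float) - src
    a = float(d @ u)
    if a <= 0:
        raise InvalidGeometryError("POI lies behind the source")
    off_x = float(d @ v) * image.sid / a  # cm, crossplane at imager plane
    off_y = float(d @ w) * image.sid / a  # cm, inplane
    if image.is_scalar:
        return float(image.pixels.ravel()[0])
    rows, cols = image.pixels.shape
    col = off_x * 10.0 / image.spacing_mm + (cols - 1) / 2.0
    row = off_y * 10.0 / image.spacing_mm + (rows - 1) / 2.0
    if not (0 <= row <= rows - 1 and 0 <= col <= cols - 1):
        raise OffImagerError(
            f"POI '{poi.label}' projects {off_x:.1f}/{off_y:.1f} cm off-axis, "
            "outside the imager panel"
        )
    return float(map_coordinates(image.pixels, [[row], [col]], order=1)[0])


def cu_to_epid_dose(cu: float, calib: CalibrationConfig, fc: float) -> float:
    """CU -> dose-to-water at imager level and depth D_max (Gy).

    ``fc`` is the absolute conversion factor in Gy per CU per unit
    ``d_calib`` (i.e. ``ConversionFactorTable.absolute``).
    """
    if cu < 0:
        raise DegenerateInputError("negative CU signal")
    if fc <= 0:
        raise DegenerateInputError("conversion factor must be positive")
    return cu * calib.d_calib * fc


def project_to_poi(d_epid: float, geometry: BeamGeometry, ftmr_val: float,
                   tmr_val: float, *, source_distance: float | None = None,
                   sid_cal: float | None = None) -> float:
    """Project the imager-level dose to a point inside the phantom (Gy).

    Inverse-square from the imager to the isocenter plane (inverting the FC
    commissioning equation), then from SAD to the point's actual source
    distance, times TMR(depth)/fTMR(thickness).  ``sid_cal`` is the SID the
    conversion factors were commissioned at (defaults to the delivery SID).
    """
    if ftmr_val <= 0 or tmr_val <= 0:
        raise DegenerateInputError("fTMR and TMR values must be positive")
    r = geometry.sad if source_distance is None else source_distance
    if r <= 0:
        raise DegenerateInputError("source-to-point distance must be positive")
    s_cal = geometry.sid if sid_cal is None else sid_cal
    return (
        d_epid
        * (geometry.sad / s_cal) ** 2
        * (geometry.sid / s_cal) ** 2
        * (geometry.sad / r) ** 2
        * tmr_val
        / ftmr_val
    )


def effective_air_gap(geometry: BeamGeometry, path: float) -> float:
    """Attenuator-exit-to-imager distance implied by the beam geometry."""
    ssd = geometry.ssd_att if geometry.ssd_att is not None else geometry.sad - path / 2.0
    return geometry.sid - ssd - path


def reconstruct_point(geometry: BeamGeometry, phantom: SlabPhantom,
                      image: PortalImage, poi: PointOfInterest,
                      tables: TableSet, calib: CalibrationConfig) -> tuple[float, bool]:
    """Reconstruct one beam's dose at one POI.

    Returns ``(dose_gy, in_aperture)``; points in the build-up region are
    rejected rather than extrapolated.
    """
    tr = trace_point(geometry, phantom, poi.position)
    if tr.depth < calib.d_max:
        raise UnsupportedRegionError(
            f"POI '{poi.label}' at radiological depth {tr.depth:.2f} cm is in "
            f"the build-up region of beam (gantry {geometry.gantry_angle:g})"
        )
    eq = geometry.eq_field
    cu = sample_cu(image, geometry, poi)
    ftmr_val = tables.ftmr.lookup(eq, tr.path, effective_air_gap(geometry, tr.path))
    tmr_val = tables.tmr.lookup(eq, tr.depth)
    fc_abs = tables.fc.absolute(eq, tr.path)
    d_epid = cu_to_epid_dose(cu, calib, fc_abs)
    dose = project_to_poi(
        d_epid, geometry, ftmr_val, tmr_val,
        source_distance=tr.source_distance, sid_cal=tables.fc.sid,
    )
    return dose, tr.in_aperture


def reconstruct_plan(plan: Plan, images: Mapping[str, PortalImage] | Iterable[PortalImage],
                     pois: Iterable[PointOfInterest], tables: TableSet,
                     calib: CalibrationConfig, phantom: SlabPhantom | None = None,
                     tps: Mapping | None = None) -> ReconstructedDose:
    """Reconstruct every (beam, POI) dose of a delivered plan.

    ``images`` maps beam ids to integrated portal images (one per beam; a
    missing image is a plan-integrity error).  Beams whose aperture excludes
    a POI's projection contribute a flagged low-confidence value.  ``tps``
    may supply reference doses keyed ``(beam_id, poi_label)``.
    """
    phantom = phantom if phantom is not None else plan.phantom
    if phantom is None:
        raise PlanIntegrityError("no phantom given and the plan carries none")
    if not isinstance(images, Mapping):
        images = {im.beam_id: im for im in images}
    pois = list(pois)
    missing = [b.beam_id for b in plan.beams if b.beam_id not in images]
    if missing:
        raise PlanIntegrityError(f"no portal image for beam(s): {', '.join(missing)}")
    out = ReconstructedDose(
        beam_ids=[b.beam_id for b in plan.beams],
        poi_labels=[p.label for p in pois],
    )
    for beam in plan.beams:
        image = images[beam.beam_id]
        for poi in pois:
            dose, in_ap = reconstruct_point(
                beam.geometry, phantom, image, poi, tables, calib
            )
            key = (beam.beam_id, poi.label)
            out.dose[key] = dose
            if not in_ap:
                out.low_confidence.add(key)
            if tps is not None and key in tps:
                out.tps[key] = float(tps[key])
    return out
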