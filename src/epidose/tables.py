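"""Dosimetric lookup tables and geometric helpers.

The transit-dosimetry formalism rests on three interpolable tables:

``FTMRTable``
    Finite tissue maximum ratio fTMR(field, thickness, air gap): the ratio of
    the dose at depth D_max with a finite absorber of thickness *t* in the
    beam to the dose without it, under otherwise identical conditions.
``TMRTable``
    Tissue maximum ratio TMR(field, depth): dose at depth relative to dose at
    D_max for the same field and source-to-point distance.
``ConversionFactorTable``
    FC(field, thickness): maps the portal imager's calibrated units (CU) to
    dose-to-water at the imager plane, normalized to 1 under reference
    conditions; the absolute Gy/CU scale of the reference cell is kept
    separately in :attr:`ConversionFactorTable.scale`.

Interpolation is log-linear along thickness/depth (attenuation in water is
near-exponential, so an exponential is interpolated exactly) and linear along
field size and air gap.  Queries up to 10% of the axis span beyond either end
extrapolate with a logged warning; beyond that they raise
:class:`~epidose.errors.OutOfRangeError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    InvalidGeometryError,
    OutOfRangeError,
    TableValidationError,
    UnsupportedRegionError,
)

logger = logging.getLogger(__name__)

#: Fraction of the axis span allowed as extrapolation beyond each axis end.
EXTRAPOLATION_MARGIN = 0.10


# ---------------------------------------------------------------------------
# configuration / geometry types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationConfig:
    """Reference calibration of the beam + imager chain.

    Parameters
    ----------
    d_calib:
        Dose in Gy delivered at depth ``d_max`` per 100 MU under reference
        conditions (10 x 10 cm^2 field, SAD setup).  1.0 for a conventionally
        calibrated linac.
    d_max:
        Depth of maximum dose in water, cm (~1.5 cm at 6 MV).
    ref_field:
        Reference square field side at SAD, cm.
    ref_sad, ref_sid:
        Reference source-to-axis and source-to-imager distances, cm.
    """

    d_calib: float = 1.0
    d_max: float = 1.5
    ref_field: float = 10.0
    ref_sad: float = 100.0
    ref_sid: float = 150.0

    def __post_init__(self):
        if self.d_calib <= 0 or self.d_max <= 0 or self.ref_field <= 0:
            raise InvalidGeometryError("d_calib, d_max and ref_field must be positive")
        if not (self.ref_sid >= self.ref_sad > 0):
            raise InvalidGeometryError("require ref_sid >= ref_sad > 0")

    def to_dict(self) -> dict:
        return {
            "schema": "calibration/1",
            "d_calib": self.d_calib,
            "d_max": self.d_max,
            "ref_field": self.ref_field,
            "ref_sad": self.ref_sad,
            "ref_sid": self.ref_sid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        return cls(
            d_calib=float(d["d_calib"]),
            d_max=float(d["d_max"]),
            ref_field=float(d["ref_field"]),
            ref_sad=float(d["ref_sad"]),
            ref_sid=float(d["ref_sid"]),
        )


@dataclass(frozen=True)
class BeamGeometry:
    """Geometry and meterset of one treatment/commissioning beam.

    Distances in cm, angles in degrees.  ``field_x``/``field_y`` are the jaw
    openings projected to the SAD plane.  ``ssd_att`` is the source-to-
    attenuator-surface distance; ``None`` means the attenuator (phantom) is
    centered at the isocenter.
    """

    sad: float = 100.0
    sid: float = 150.0
    ssd_att: float | None = None
    gantry_angle: float = 0.0
    field_x: float = 10.0
    field_y: float = 10.0
    mu: float = 100.0
    energy_label: str = "6MV"

    def __post_init__(self):
        if self.sad <= 0 or self.sid <= self.sad:
            raise InvalidGeometryError(
                f"require sid > sad > 0, got sad={self.sad}, sid={self.sid}"
            )
        if self.field_x <= 0 or self.field_y <= 0:
            raise InvalidGeometryError("field_x and field_y must be positive")
        if self.mu < 0:
            raise InvalidGeometryError("mu must be non-negative")
        if not 0 <= self.gantry_angle < 360:
            raise InvalidGeometryError("gantry_angle must lie in [0, 360)")
        if self.ssd_att is not None and self.ssd_att <= 0:
            raise InvalidGeometryError("ssd_att must be positive when given")

    @property
    def eq_field(self) -> float:
        return equivalent_square(self.field_x, self.field_y)

    def to_dict(self) -> dict:
        return {
            "sad": self.sad,
            "sid": self.sid,
            "ssd_att": self.ssd_att,
            "gantry_angle": self.gantry_angle,
            "field_x": self.field_x,
            "field_y": self.field_y,
            "mu": self.mu,
            "energy_label": self.energy_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamGeometry":
        ssd = d.get("ssd_att")
        return cls(
            sad=float(d["sad"]),
            sid=float(d["sid"]),
            ssd_att=None if ssd is None else float(ssd),
            gantry_angle=float(d.get("gantry_angle", 0.0)),
            field_x=float(d["field_x"]),
            field_y=float(d["field_y"]),
            mu=float(d.get("mu", 0.0)),
            energy_label=str(d.get("energy_label", "6MV")),
        )


def equivalent_square(field_x: float, field_y: float) -> float:
    """Equivalent square side of a rectangular field (Sterling 4A/P rule).

    ``2 * x * y / (x + y)``; a square maps to itself.
    """
    if field_x <= 0 or field_y <= 0:
        raise InvalidGeometryError(
            f"field sides must be positive, got {field_x} x {field_y}"
        )
    return 2.0 * field_x * field_y / (field_x + field_y)


# ---------------------------------------------------------------------------
# interpolation core
# ---------------------------------------------------------------------------


def _axis(values: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise TableValidationError(f"axis '{name}' must be a non-empty 1-D vector")
    if a.size > 1 and not np.all(np.diff(a) > 0):
        raise TableValidationError(f"axis '{name}' must be strictly increasing")
    return a


def _bracket(axis: np.ndarray, x: float, axis_name: str, table_name: str):
    """Bracket *x* on *axis*; returns ``(i0, i1, w)`` with weight w toward i1.

    Exact at nodes (w is exactly 0.0 or 1.0).  Within the extrapolation
    margin the edge pair is extended with a logged warning.
    """
    n = axis.size
    if n == 1:
        return 0, 0, 0.0
    lo, hi = float(axis[0]), float(axis[-1])
    span = hi - lo
    margin = EXTRAPOLATION_MARGIN * span
    if x < lo - margin or x > hi + margin:
        raise OutOfRangeError(
            f"{table_name}: {axis_name}={x:g} outside [{lo:g}, {hi:g}] "
            f"plus the {EXTRAPOLATION_MARGIN:.0%} extrapolation margin"
        )
    if x < lo or x > hi:
        logger.warning(
            "%s: extrapolating %s=%g beyond [%g, %g]", table_name, axis_name, x, lo, hi
        )
    i1 = int(np.searchsorted(axis, x))
    i1 = min(max(i1, 1), n - 1)
    i0 = i1 - 1
    w = (x - axis[i0]) / (axis[i1] - axis[i0])
    return i0, i1, float(w)


def _interp(values: np.ndarray, brackets, log_axes) -> float:
    """Tensor-product interpolation with per-axis log/linear rules.

    Log axes are reduced first so that along them ln(value) is interpolated
    linearly.  Node queries reproduce stored values exactly (the w in {0, 1}
    branches bypass the exp/log round trip).
    """
    idx = np.ix_(*[[b[0], b[1]] for b in brackets])
    sub = np.asarray(values, dtype=float)[idx]
    order = sorted(range(len(brackets)), key=lambda ax: not log_axes[ax])
    for ax in order:
        i0, i1, w = brackets[ax]
        a = np.take(sub, 0, axis=ax)
        b = np.take(sub, -1, axis=ax)
        if i0 == i1 or w == 0.0:
            r = a
        elif w == 1.0:
            r = b
        elif log_axes[ax]:
            r = np.exp((1.0 - w) * np.log(a) + w * np.log(b))
        else:
            r = (1.0 - w) * a + w * b
        sub = np.expand_dims(r, ax)
    return float(sub.reshape(()))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclass
class FTMRTable:
    """fTMR grid over (equivalent field side, absorber thickness, air gap).

    ``values`` has shape ``(n_fields, n_thicknesses, n_gaps)``.  A singleton
    air-gap axis means the commissioning data did not resolve the gap
    dependence; lookups then ignore the requested gap.
    """

    fields: np.ndarray
    thicknesses: np.ndarray
    air_gaps: np.ndarray
    values: np.ndarray
    sid: float = 150.0

    def __post_init__(self):
        self.fields = _axis(self.fields, "field")
        self.thicknesses = _axis(self.thicknesses, "thickness")
        self.air_gaps = _axis(self.air_gaps, "air_gap")
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        v = self.values
        expected = (self.fields.size, self.thicknesses.size, self.air_gaps.size)
        if v.shape != expected:
            raise TableValidationError(
                f"fTMR values shape {v.shape} does not match axes {expected}"
            )
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise TableValidationError("fTMR values must lie in (0, 1]")
        if np.any(self.thicknesses < 0):
            raise TableValidationError("absorber thickness axis must be >= 0")
        t0 = np.flatnonzero(self.thicknesses == 0)
        if t0.size and not np.allclose(v[:, t0[0], :], 1.0, atol=1e-9):
            raise TableValidationError("fTMR at thickness 0 must equal 1 exactly")
        if self.thicknesses.size > 1 and not np.all(np.diff(v, axis=1) < 0):
            raise TableValidationError(
                "fTMR must strictly decrease with absorber thickness"
            )
        if self.fields.size > 1 and not np.all(np.diff(v, axis=0) >= -1e-9):
            raise TableValidationError(
                "fTMR must be non-decreasing with field size (scatter)"
            )

    def lookup(self, eq_field: float, thickness: float, air_gap: float | None = None) -> float:
        """Interpolated fTMR; exactly 1 for ``thickness == 0``."""
        if thickness < 0:
            raise OutOfRangeError(f"fTMR: thickness={thickness:g} must be >= 0")
        if thickness == 0:
            return 1.0
        bf = _bracket(self.fields, eq_field, "field", "fTMR")
        bt = _bracket(self.thicknesses, thickness, "thickness", "fTMR")
        if self.air_gaps.size == 1 or air_gap is None:
            bg = (0, 0, 0.0)
        else:
            bg = _bracket(self.air_gaps, air_gap, "air_gap", "fTMR")
        return _interp(self.values, (bf, bt, bg), (False, True, False))

    def to_dict(self) -> dict:
        return {
            "schema": "ftmr-table/1",
            "fields": self.fields.tolist(),
            "thicknesses": self.thicknesses.tolist(),
            "air_gaps": self.air_gaps.tolist(),
            "values": self.values.ravel().tolist(),
            "sid": self.sid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FTMRTable":
        shape = (len(d["fields"]), len(d["thicknesses"]), len(d["air_gaps"]))
        return cls(
            fields=np.asarray(d["fields"], float),
            thicknesses=np.asarray(d["thicknesses"], float),
            air_gaps=np.asarray(d["air_gaps"], float),
            values=np.asarray(d["values"], float).reshape(shape),
            sid=float(d.get("sid", 150.0)),
        )


@dataclass
class TMRTable:
    """TMR grid over (equivalent field side, depth); ``values`` (n_f, n_d)."""

    fields: np.ndarray
    depths: np.ndarray
    values: np.ndarray
    d_max: float = 1.5

    def __post_init__(self):
        self.fields = _axis(self.fields, "field")
        self.depths = _axis(self.depths, "depth")
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        v = self.values
        expected = (self.fields.size, self.depths.size)
        if v.shape != expected:
            raise TableValidationError(
                f"TMR values shape {v.shape} does not match axes {expected}"
            )
        if self.depths[0] < self.d_max - 1e-9:
            raise TableValidationError(
                f"TMR depth axis starts at {self.depths[0]:g} < d_max={self.d_max:g}"
            )
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise TableValidationError("TMR values must lie in (0, 1] for depth >= d_max")
        if abs(self.depths[0] - self.d_max) < 1e-9 and not np.allclose(
            v[:, 0], 1.0, atol=1e-9
        ):
            raise TableValidationError("TMR at depth d_max must equal 1 exactly")
        if self.depths.size > 1 and not np.all(np.diff(v, axis=1) < 0):
            raise TableValidationError("TMR must strictly decrease with depth")

    def lookup(self, eq_field: float, depth: float) -> float:
        """Interpolated TMR; exactly 1 at ``depth == d_max``.

        Depths shallower than D_max (build-up region) are rejected.
        """
        if depth < self.d_max - 1e-9:
            raise UnsupportedRegionError(
                f"depth {depth:g} cm is in the build-up region (< d_max={self.d_max:g})"
            )
        if abs(depth - self.d_max) < 1e-12:
            return 1.0
        bf = _bracket(self.fields, eq_field, "field", "TMR")
        bd = _bracket(self.depths, depth, "depth", "TMR")
        return _interp(self.values, (bf, bd), (False, True))

    def to_dict(self) -> dict:
        return {
            "schema": "tmr-table/1",
            "fields": self.fields.tolist(),
            "depths": self.depths.tolist(),
            "values": self.values.ravel().tolist(),
            "d_max": self.d_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TMRTable":
        shape = (len(d["fields"]), len(d["depths"]))
        return cls(
            fields=np.asarray(d["fields"], float),
            depths=np.asarray(d["depths"], float),
            values=np.asarray(d["values"], float).reshape(shape),
            d_max=float(d.get("d_max", 1.5)),
        )


@dataclass
class ConversionFactorTable:
    """Conversion factors FC over (equivalent field side, absorber thickness).

    Stored values are normalized so the reference cell equals 1; the absolute
    Gy-per-CU figure of the reference cell (per unit ``d_calib``) is kept in
    :attr:`scale`, so ``absolute(f, t) = scale * lookup(f, t)``.  ``sid`` and
    ``sad`` record the commissioning geometry the factors were measured in.
    """

    fields: np.ndarray
    thicknesses: np.ndarray
    values: np.ndarray
    scale: float = 1.0
    sid: float = 150.0
    sad: float = 100.0
    ref_field: float = 10.0
    ref_thickness: float | None = None

    def __post_init__(self):
        self.fields = _axis(self.fields, "field")
        self.thicknesses = _axis(self.thicknesses, "thickness")
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        expected = (self.fields.size, self.thicknesses.size)
        if self.values.shape != expected:
            raise TableValidationError(
                f"FC values shape {self.values.shape} does not match axes {expected}"
            )
        if np.any(self.values <= 0):
            raise TableValidationError("FC values must be positive")
        if self.scale <= 0:
            raise TableValidationError("FC scale must be positive")

    def lookup(self, eq_field: float, thickness: float) -> float:
        """Bilinear-interpolated normalized FC (> 0)."""
        bf = _bracket(self.fields, eq_field, "field", "FC")
        bt = _bracket(self.thicknesses, thickness, "thickness", "FC")
        return _interp(self.values, (bf, bt), (False, False))

    def absolute(self, eq_field: float, thickness: float) -> float:
        """FC in Gy per CU per unit ``d_calib``."""
        return self.scale * self.lookup(eq_field, thickness)

    def renormalized(self) -> "ConversionFactorTable":
        """Re-split values/scale so the reference cell is exactly 1."""
        fi = int(np.argmin(np.abs(self.fields - self.ref_field)))
        rt = self.ref_thickness if self.ref_thickness is not None else self.thicknesses[0]
        ti = int(np.argmin(np.abs(self.thicknesses - rt)))
        ref = float(self.values[fi, ti])
        return replace(self, values=self.values / ref, scale=self.scale * ref)

    def to_dict(self) -> dict:
        return {
            "schema": "fc-table/1",
            "fields": self.fields.tolist(),
            "thicknesses": self.thicknesses.tolist(),
            "values": self.values.ravel().tolist(),
            "scale": self.scale,
            "sid": self.sid,
            "sad": self.sad,
            "ref_field": self.ref_field,
            "ref_thickness": self.ref_thickness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionFactorTable":
        shape = (len(d["fields"]), len(d["thicknesses"]))
        rt = d.get("ref_thickness")
        return cls(
            fields=np.asarray(d["fields"], float),
            thicknesses=np.asarray(d["thicknesses"], float),
            values=np.asarray(d["values"], float).reshape(shape),
            scale=float(d.get("scale", 1.0)),
            sid=float(d.get("sid", 150.0)),
            sad=float(d.get("sad", 100.0)),
            ref_field=float(d.get("ref_field", 10.0)),
            ref_thickness=None if rt is None else float(rt),
        )


@dataclass
class TableSet:
    """The commissioned table triple a reconstruction needs."""

    ftmr: FTMRTable
    tmr: TMRTable
    fc: ConversionFactorTable


# thin functional aliases matching the operation names -----------------------


def ftmr_lookup(table: FTMRTable, eq_field: float, thickness: float,
                air_gap: float | None = None) -> float:
    return table.lookup(eq_field, thickness, air_gap)


def tmr_lookup(table: TMRTable, eq_field: float, depth: float) -> float:
    return table.lookup(eq_field, depth)


def fc_lookup(table: ConversionFactorTable, eq_field: float, thickness: float) -> float:
    return table.lookup(eq_field, thickness)
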