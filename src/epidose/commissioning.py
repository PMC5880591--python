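"""Build fTMR and conversion-factor tables from commissioning measurements.

An fTMR cell is the ratio of two ion-chamber doses at depth D_max — one with
a finite solid-water absorber in the beam, one without, under otherwise
identical conditions.  Conversion factors FC come from the commissioning
equation

    FC = D_TPS / (D_calib * CU) * (SID/SAD)^2 * fTMR / TMR,

evaluated per (field size, phantom thickness) cell and normalized to the
reference cell, followed by an iterative correction that multiplies each
cell by D_TPS / D_recon for its setup until the reconstruction of the
commissioning deliveries reproduces the planning-system doses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    ConvergenceError,
    IncompleteGridError,
    PairingError,
    ValidationFailure,
)
from .reconstruction import cu_to_epid_dose, project_to_poi
from .tables import (
    BeamGeometry,
    CalibrationConfig,
    ConversionFactorTable,
    FTMRTable,
    TMRTable,
)

logger = logging.getLogger(__name__)

#: duplicate measurements whose relative spread exceeds this trigger a warning
DUPLICATE_SPREAD_WARN = 0.01


@dataclass(frozen=True)
class MeasurementRecord:
    """One commissioning acquisition: setup, chamber dose at D_max, and CU."""

    geometry: BeamGeometry
    thickness: float            # cm of absorber; 0 for the open reference
    chamber_dose: float         # Gy at D_max in virtual water
    cu: float                   # calibrated units at the image center
    role: str = "with-absorber"  # with-absorber | open-reference

    def __post_init__(self):
        if self.chamber_dose <= 0 or self.cu <= 0:
            raise ValidationFailure("chamber_dose and cu must be positive")
        if self.thickness < 0:
            raise ValidationFailure("thickness must be >= 0")
        if self.role not in ("with-absorber", "open-reference"):
            raise ValidationFailure(f"unknown record role '{self.role}'")
        if self.role == "open-reference" and self.thickness != 0:
            raise ValidationFailure("open-reference records must have thickness 0")

    @property
    def air_gap(self) -> float:
        """Attenuator-exit-to-imager distance for this setup."""
        g = self.geometry
        ssd = g.ssd_att if g.ssd_att is not None else g.sad - self.thickness / 2.0
        return g.sid - ssd - self.thickness

    def to_dict(self) -> dict:
        return {
            "schema": "measurement-record/1",
            "geometry": self.geometry.to_dict(),
            "thickness": self.thickness,
            "chamber_dose": self.chamber_dose,
            "cu": self.cu,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementRecord":
        return cls(
            geometry=BeamGeometry.from_dict(d["geometry"]),
            thickness=float(d["thickness"]),
            chamber_dose=float(d["chamber_dose"]),
            cu=float(d["cu"]),
            role=str(d.get("role", "with-absorber")),
        )


@dataclass(frozen=True)
class TPSReferencePoint:
    """Planning-system dose at the isocenter of one commissioning setup."""

    field: float                # equivalent square field side, cm at SAD
    thickness: float            # phantom thickness, cm
    d_tps: float                # Gy at isocenter
    depth: float | None = None  # isocenter depth; default thickness / 2

    def __post_init__(self):
        if self.d_tps <= 0:
            raise DegenerateInputError("d_tps must be positive")

    @property
    def iso_depth(self) -> float:
        return self.thickness / 2.0 if self.depth is None else self.depth

    def to_dict(self) -> dict:
        return {
            "schema": "tps-point/1",
            "field": self.field,
            "thickness": self.thickness,
            "d_tps": self.d_tps,
            "depth": self.depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TPSReferencePoint":
        dp = d.get("depth")
        return cls(
            field=float(d["field"]),
            thickness=float(d["thickness"]),
            d_tps=float(d["d_tps"]),
            depth=None if dp is None else float(dp),
        )


# ---------------------------------------------------------------------------
# fTMR derivation
# ---------------------------------------------------------------------------


def _mean_with_spread_warning(vals: Sequence[float], what: str) -> float:
    vals = np.asarray(vals, float)
    m = float(vals.mean())
    if vals.size > 1 and m > 0:
        spread = (vals.max() - vals.min()) / m
        if spread > DUPLICATE_SPREAD_WARN:
            logger.warning("%s: duplicate spread %.2f%% exceeds %.0f%%; using mean",
                           what, 100 * spread, 100 * DUPLICATE_SPREAD_WARN)
    return m


def derive_ftmr(records: Iterable[MeasurementRecord]) -> FTMRTable:
    """Derive the fTMR table from paired with/without-absorber chamber doses.

    Every with-absorber record needs an open-reference record at the same
    field size and (SAD, SID); duplicates are averaged.  If the observed
    (field, thickness, air gap) cells do not form a complete 3-D grid — the
    default protocol measures one SSD_att per thickness, so gaps differ
    across thicknesses — the air-gap axis is collapsed to a singleton
    (values averaged per (field, thickness), warning on >1% spread).  A
    thickness-0 plane of exact ones is always included.
    """
    records = list(records)
    open_ref: dict[tuple, list[float]] = {}
    for r in records:
        if r.role == "open-reference":
            key = (round(r.geometry.eq_field, 3), r.geometry.sad, r.geometry.sid)
            open_ref.setdefault(key, []).append(r.chamber_dose)
    cells: dict[tuple, list[float]] = {}
    sid = None
    for r in records:
        if r.role != "with-absorber":
            continue
        key = (round(r.geometry.eq_field, 3), r.geometry.sad, r.geometry.sid)
        if key not in open_ref:
            raise PairingError(
                f"no open-reference record for field {key[0]:g} cm at "
                f"SAD {key[1]:g} / SID {key[2]:g}"
            )
        d_open = float(np.mean(open_ref[key]))
        cell = (round(r.geometry.eq_field, 3), round(r.thickness, 3),
                round(r.air_gap, 1))
        cells.setdefault(cell, []).append(r.chamber_dose / d_open)
        sid = r.geometry.sid
    if not cells:
        raise PairingError("no with-absorber records to derive fTMR from")

    fields = sorted({c[0] for c in cells})
    thicknesses = sorted({c[1] for c in cells})
    gaps = sorted({c[2] for c in cells})
    complete = all(
        (f, t, g) in cells for f in fields for t in thicknesses for g in gaps
    )
    if complete and len(gaps) > 1:
        values = np.empty((len(fields), len(thicknesses), len(gaps)))
        for i, f in enumerate(fields):
            for j, t in enumerate(thicknesses):
                for k, g in enumerate(gaps):
                    values[i, j, k] = _mean_with_spread_warning(
                        cells[(f, t, g)], f"fTMR cell ({f:g}, {t:g}, {g:g})"
                    )
        gap_axis = np.asarray(gaps, float)
    else:
        values = np.empty((len(fields), len(thicknesses), 1))
        for i, f in enumerate(fields):
            for j, t in enumerate(thicknesses):
                ratios = [v for (cf, ct, _), vs in cells.items()
                          if cf == f and ct == t for v in vs]
                if not ratios:
                    raise IncompleteGridError(
                        f"no fTMR measurement for field {f:g} cm, thickness {t:g} cm"
                    )
                values[i, j, 0] = _mean_with_spread_warning(
                    ratios, f"fTMR cell ({f:g}, {t:g})"
                )
        gap_axis = np.asarray([float(np.median(gaps))])

    # prepend the exact open-field plane
    if 0.0 not in thicknesses:
        thicknesses = [0.0] + thicknesses
        values = np.concatenate(
            [np.ones((len(fields), 1, values.shape[2])), values], axis=1
        )
    return FTMRTable(
        fields=np.asarray(fields, float),
        thicknesses=np.asarray(thicknesses, float),
        air_gaps=gap_axis,
        values=values,
        sid=float(sid),
    )


# ---------------------------------------------------------------------------
# conversion factors
# ---------------------------------------------------------------------------


def compute_fc(rec: TPSReferencePoint, calib: CalibrationConfig, cu: float,
               geometry: BeamGeometry, ftmr: float, tmr: float) -> float:
    """One raw conversion factor from the commissioning equation."""
    if cu <= 0:
        raise DegenerateInputError("CU must be positive to compute a conversion factor")
    if tmr <= 0 or ftmr <= 0:
        raise DegenerateInputError("fTMR and TMR must be positive")
    return (
        rec.d_tps / (calib.d_calib * cu)
        * (geometry.sid / geometry.sad) ** 2
        * ftmr / tmr
    )


def build_fc_table(records: Iterable[MeasurementRecord],
                   tps_points: Iterable[TPSReferencePoint],
                   calib: CalibrationConfig,
                   ftmr_table: FTMRTable,
                   tmr_table: TMRTable,
                   ref_thickness: float | None = None) -> ConversionFactorTable:
    """Conversion-factor grid over the TPS commissioning (field, thickness) cells.

    Each cell gets the mean ``compute_fc`` over matching records (warned if
    duplicates spread >1%); the table is then normalized so the reference
    cell — (ref_field, smallest thickness) by default — equals 1, the raw
    Gy/CU figure of that cell going to ``scale``.
    """
    tps_points = list(tps_points)
    records = [r for r in records if r.role == "with-absorber"]
    if not tps_points:
        raise IncompleteGridError("no TPS reference points supplied")
    fields = sorted({round(p.field, 3) for p in tps_points})
    thicknesses = sorted({round(p.thickness, 3) for p in tps_points})
    tps_by_cell = {(round(p.field, 3), round(p.thickness, 3)): p for p in tps_points}

    rec_by_cell: dict[tuple, list[MeasurementRecord]] = {}
    for r in records:
        rec_by_cell.setdefault(
            (round(r.geometry.eq_field, 3), round(r.thickness, 3)), []
        ).append(r)

    raw = np.empty((len(fields), len(thicknesses)))
    missing = []
    sid = sad = None
    for i, f in enumerate(fields):
        for j, t in enumerate(thicknesses):
            cell = (f, t)
            if cell not in tps_by_cell or cell not in rec_by_cell:
                missing.append(f"(field {f:g}, thickness {t:g})")
                continue
            tp = tps_by_cell[cell]
            fcs = []
            for r in rec_by_cell[cell]:
                ftmr = ftmr_table.lookup(f, t, r.air_gap)
                tmr = tmr_table.lookup(f, tp.iso_depth)
                fcs.append(compute_fc(tp, calib, r.cu, r.geometry, ftmr, tmr))
                sid, sad = r.geometry.sid, r.geometry.sad
            raw[i, j] = _mean_with_spread_warning(fcs, f"FC cell ({f:g}, {t:g})")
    if missing:
        raise IncompleteGridError(
            "commissioning grid cells without both a record and a TPS point: "
            + ", ".join(missing)
        )
    table = ConversionFactorTable(
        fields=np.asarray(fields, float),
        thicknesses=np.asarray(thicknesses, float),
        values=raw,
        scale=1.0,
        sid=float(sid),
        sad=float(sad),
        ref_field=calib.ref_field,
        ref_thickness=ref_thickness,
    )
    return table.renormalized()


def commissioning_reconstructor(records: Iterable[MeasurementRecord],
                                calib: CalibrationConfig,
                                ftmr_table: FTMRTable,
                                tmr_table: TMRTable) -> Callable:
    """Closure reconstructing the isocenter dose of a commissioning setup.

    Returns ``f(tps_point, fc_table) -> Gy`` running the standard CU ->
    imager dose -> isocenter projection chain on the recorded CU of the
    matching (field, thickness) setup.  This is what the iterative TPS
    correction drives toward the planning-system doses.
    """
    by_cell: dict[tuple, list[MeasurementRecord]] = {}
    for r in records:
        if r.role == "with-absorber":
            by_cell.setdefault(
                (round(r.geometry.eq_field, 3), round(r.thickness, 3)), []
            ).append(r)

    def reconstruct(tp: TPSReferencePoint, fc_table: ConversionFactorTable) -> float:
        cell = (round(tp.field, 3), round(tp.thickness, 3))
        if cell not in by_cell:
            raise IncompleteGridError(
                f"no commissioning record for field {tp.field:g}, "
                f"thickness {tp.thickness:g}"
            )
        recs = by_cell[cell]
        cu = float(np.mean([r.cu for r in recs]))
        g = recs[0].geometry
        ftmr = ftmr_table.lookup(tp.field, tp.thickness, recs[0].air_gap)
        tmr = tmr_table.lookup(tp.field, tp.iso_depth)
        d_epid = cu_to_epid_dose(cu, calib, fc_table.absolute(tp.field, tp.thickness))
        return project_to_poi(d_epid, g, ftmr, tmr, sid_cal=fc_table.sid)

    return reconstruct


def adjust_fc_with_tps(fc_table: ConversionFactorTable,
                       tps_points: Iterable[TPSReferencePoint],
                       reconstructor: Callable,
                       tol: float = 1e-4,
                       max_iter: int = 50) -> tuple[ConversionFactorTable, np.ndarray]:
    """Iterative TPS-based correction of the conversion factors.

    Each cell is multiplied by ``D_TPS / D_recon`` for its setup until the
    largest per-cell relative change drops below ``tol`` (or the iteration
    cap is hit, which raises :class:`ConvergenceError` carrying the
    residuals).  Returns the corrected, renormalized table and the final
    per-cell residuals ``|D_TPS/D_recon - 1|``.
    """
    pts = list(tps_points)
    table = replace(fc_table, values=fc_table.values.copy())
    idx = []
    for p in pts:
        if p.d_tps <= 0:
            raise DegenerateInputError(
                f"TPS dose for field {p.field:g}, thickness {p.thickness:g} is not positive"
            )
        fi = np.flatnonzero(np.isclose(table.fields, p.field))
        tj = np.flatnonzero(np.isclose(table.thicknesses, p.thickness))
        if fi.size == 0 or tj.size == 0:
            raise IncompleteGridError(
                f"TPS point (field {p.field:g}, thickness {p.thickness:g}) "
                "is not on the conversion-factor grid"
            )
        idx.append((int(fi[0]), int(tj[0])))

    residuals = np.zeros(len(pts))
    for iteration in range(max_iter + 1):
        factors = np.empty(len(pts))
        for k, p in enumerate(pts):
            d_recon = reconstructor(p, table)
            if d_recon <= 0:
                raise DegenerateInputError(
                    f"reconstructed dose is not positive for field {p.field:g}, "
                    f"thickness {p.thickness:g}"
                )
            factors[k] = p.d_tps / d_recon
        residuals = np.abs(factors - 1.0)
        if residuals.max() < tol:
            logger.info("TPS correction converged after %d iteration(s); "
                        "max residual %.2e", iteration, residuals.max())
            break
        if iteration == max_iter:
            raise ConvergenceError(
                f"TPS correction did not converge within {max_iter} iterations "
                f"(max residual {residuals.max():.3e})",
                residuals=residuals,
            )
        for k, (i, j) in enumerate(idx):
            table.values[i, j] *= factors[k]
    return table.renormalized(), residuals
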