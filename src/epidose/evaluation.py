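"""Deviation reports, thresholds, MU-sensitivity and automatic POI placement.

Deviations are *local*: 100 * (D_recon - D_TPS) / D_TPS per beam and point;
negative means the reconstruction underestimates the planned dose.  Per-POI
summaries give the arithmetic mean and sample SD (n-1) over beams plus the
total-dose deviation.  Default thresholds: 5% on the per-POI total dose
(plan-level notification), 8% per individual beam (warning); beams
contributing less than 10% of a POI's total reference dose are flagged
low-dose and excluded from pass/fail, since low-dose regions make poor
evaluation points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SamplingError, UndefinedReferenceError
from .reconstruction import DoseGrid, PointOfInterest, ReconstructedDose

PLAN_THRESHOLD = 5.0      # % on the per-POI total-dose deviation
BEAM_THRESHOLD = 8.0      # % on an individual beam's deviation
LOW_DOSE_FRACTION = 0.10  # beams below this share of a POI's TPS dose are excluded


def local_deviation(d_recon: float, d_tps: float) -> float:
    """Local percent deviation 100*(d_recon - d_tps)/d_tps."""
    if d_tps <= 0:
        raise UndefinedReferenceError(
            "reference dose is zero or negative; deviation undefined"
        )
    return 100.0 * (d_recon - d_tps) / d_tps


def plan_summary(d_recon: Sequence[float], d_tps: Sequence[float]) -> dict:
    """Mean/SD of per-beam local deviations plus the total-dose deviation.

    The total-dose deviation (deviation of the summed doses) equals the
    TPS-dose-weighted mean of the per-beam local deviations; both labels are
    reported with that single value.  SD uses the n-1 (sample) convention
    and is 0 for a single beam.
    """
    d_recon = np.asarray(d_recon, float)
    d_tps = np.asarray(d_tps, float)
    if d_recon.size == 0:
        raise DegenerateInputError("no beams to summarize (all excluded?)")
    devs = np.array([local_deviation(a, b) for a, b in zip(d_recon, d_tps)])
    total_dev = local_deviation(float(d_recon.sum()), float(d_tps.sum()))
    return {
        "mean": float(devs.mean()),
        "sd": float(devs.std(ddof=1)) if devs.size > 1 else 0.0,
        "total_deviation": total_dev,
        "weighted_mean_deviation": total_dev,
        "n_beams": int(devs.size),
    }


def mu_sensitivity(baseline_mean_dev: float, mu_scale: float) -> float:
    """Mean deviation expected when the delivered MU are scaled by ``mu_scale``.

    Delivery scaling compounds multiplicatively with the plan's baseline
    systematic deviation: ``100 * (mu_scale * (1 + baseline/100) - 1)``.
    A -0.6% baseline with a 5% MU cut gives -5.57 ~ -5.6%.
    """
    if mu_scale <= 0:
        raise DegenerateInputError("mu_scale must be positive")
    return 100.0 * (mu_scale * (1.0 + baseline_mean_dev / 100.0) - 1.0)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class ReportRow:
    beam_id: str
    poi: str
    d_recon: float
    d_tps: float | None
    deviation: float | None
    flag: str  # ok | warn | low-dose | no-reference | low-confidence

    def to_dict(self) -> dict:
        return {
            "beam_id": self.beam_id, "poi": self.poi,
            "d_recon": self.d_recon, "d_tps": self.d_tps,
            "deviation": self.deviation, "flag": self.flag,
        }


@dataclass
class DeviationReport:
    """Per-(beam, POI) deviations with per-POI summaries and pass/fail flags."""

    rows: list[ReportRow]
    poi_summary: dict
    plan_threshold: float = PLAN_THRESHOLD
    beam_threshold: float = BEAM_THRESHOLD
    low_dose_frac: float = LOW_DOSE_FRACTION

    @property
    def passed(self) -> bool:
        return all(s["status"] == "pass" for s in self.poi_summary.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.poi_summary).T

    def render_text(self) -> str:
        lines = ["Per-beam local deviations (%):",
                 self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
                 "", "Per-POI summary:",
                 self.summary_frame().to_string(float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema": "report/1",
            "plan_threshold": self.plan_threshold,
            "beam_threshold": self.beam_threshold,
            "low_dose_frac": self.low_dose_frac,
            "rows": [r.to_dict() for r in self.rows],
            "poi_summary": self.poi_summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviationReport":
        rows = [ReportRow(**{k: r.get(k) for k in
                             ("beam_id", "poi", "d_recon", "d_tps", "deviation", "flag")})
                for r in d["rows"]]
        return cls(
            rows=rows,
            poi_summary=dict(d["poi_summary"]),
            plan_threshold=float(d.get("plan_threshold", PLAN_THRESHOLD)),
            beam_threshold=float(d.get("beam_threshold", BEAM_THRESHOLD)),
            low_dose_frac=float(d.get("low_dose_frac", LOW_DOSE_FRACTION)),
        )


def build_report(recon: ReconstructedDose,
                 plan_threshold: float = PLAN_THRESHOLD,
                 beam_threshold: float = BEAM_THRESHOLD,
                 low_dose_frac: float = LOW_DOSE_FRACTION) -> DeviationReport:
    """Score a reconstruction against its attached TPS reference doses.

    Per POI: beams contributing < ``low_dose_frac`` of the POI's total TPS
    dose are marked ``low-dose`` and excluded from the mean/SD, the total-
    dose deviation, and pass/fail; remaining beams get ``warn`` when their
    |deviation| exceeds ``beam_threshold``; the POI fails when its
    |total-dose deviation| (non-excluded beams) exceeds ``plan_threshold``.
    """
    if plan_threshold <= 0 or beam_threshold <= 0:
        raise DegenerateInputError("thresholds must be positive")
    rows: list[ReportRow] = []
    poi_summary: dict = {}
    for label in recon.poi_labels:
        beams = recon.beam_ids
        tps = {b: recon.tps.get((b, label)) for b in beams}
        if any(v is None for v in tps.values()):
            for b in beams:
                rows.append(ReportRow(b, label, recon.dose[(b, label)],
                                      tps[b], None, "no-reference"))
            poi_summary[label] = {"status": "no-reference"}
            continue
        total_tps = sum(tps.values())
        kept_recon, kept_tps = [], []
        for b in beams:
            d_r = recon.dose[(b, label)]
            d_t = tps[b]
            if d_t <= 0 or (total_tps > 0 and d_t < low_dose_frac * total_tps):
                dev = local_deviation(d_r, d_t) if d_t > 0 else None
                rows.append(ReportRow(b, label, d_r, d_t, dev, "low-dose"))
                continue
            dev = local_deviation(d_r, d_t)
            flag = "warn" if abs(dev) > beam_threshold else "ok"
            if (b, label) in recon.low_confidence:
                flag = "low-confidence"
            rows.append(ReportRow(b, label, d_r, d_t, dev, flag))
            kept_recon.append(d_r)
            kept_tps.append(d_t)
        if not kept_recon:
            poi_summary[label] = {"status": "all-excluded"}
            continue
        summary = plan_summary(kept_recon, kept_tps)
        summary["status"] = (
            "fail" if abs(summary["total_deviation"]) > plan_threshold else "pass"
        )
        poi_summary[label] = summary
    return DeviationReport(rows, poi_summary, plan_threshold, beam_threshold,
                           low_dose_frac)


def flag_deviations(recon: ReconstructedDose,
                    plan_threshold: float = PLAN_THRESHOLD,
                    beam_threshold: float = BEAM_THRESHOLD,
                    low_dose_frac: float = LOW_DOSE_FRACTION) -> dict:
    """Flags only: {(beam, poi): flag} plus {poi: status}."""
    report = build_report(recon, plan_threshold, beam_threshold, low_dose_frac)
    return {
        "beam_flags": {(r.beam_id, r.poi): r.flag for r in report.rows},
        "poi_status": {k: v["status"] for k, v in report.poi_summary.items()},
    }


# ---------------------------------------------------------------------------
# automatic POI placement
# ---------------------------------------------------------------------------


def auto_poi_sample(dose_grid: DoseGrid, n: int = 20,
                    high_dose_frac: float = 0.90,
                    seed: int | None = None) -> list[PointOfInterest]:
    """Draw ``n`` distinct points uniformly from the high-dose region.

    The high-dose region is every voxel with dose >= ``high_dose_frac`` times
    the grid maximum — a stand-in for "inside the prescription target
    volume" when no structure set is available.  Reproducible for a given
    seed.
    """
    v = dose_grid.values
    if not np.any(v > 0):
        raise SamplingError("dose grid is empty")
    qualifying = np.argwhere(v >= high_dose_frac * v.max())
    if qualifying.shape[0] < n:
        raise SamplingError(
            f"only {qualifying.shape[0]} voxels at >= {high_dose_frac:.0%} of the "
            f"maximum dose; lower high_dose_frac or request fewer than {n} points"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(qualifying.shape[0], size=n, replace=False)
    pois = []
    for k, row in enumerate(qualifying[picks]):
        pos = dose_grid.voxel_position(row)
        pois.append(PointOfInterest(
            label=f"auto-{k + 1:02d}",
            position=(float(pos[0]), float(pos[1]), float(pos[2])),
            role="target",
        ))
    return pois
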