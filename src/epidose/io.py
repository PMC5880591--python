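"""Versioned JSON fixture I/O.

Every fixture document is self-describing through a ``schema`` key
(``ftmr-table/1``, ``plan/1``, ...).  Files holding one document are plain
JSON; record streams (measurement records, TPS points) are JSON lines, one
self-describing object per line.  All type invariants are enforced when a
fixture is loaded.
"""

from __future__ import annotations

import json
from pathlib import Path

from .commissioning import MeasurementRecord, TPSReferencePoint
from .errors import FixtureFormatError
from .evaluation import DeviationReport
from .reconstruction import DoseGrid, Plan, PointOfInterest, PortalImage, ReconstructedDose
from .tables import CalibrationConfig, ConversionFactorTable, FTMRTable, TMRTable

_PARSERS = {
    "ftmr-table/1": FTMRTable.from_dict,
    "tmr-table/1": TMRTable.from_dict,
    "fc-table/1": ConversionFactorTable.from_dict,
    "calibration/1": CalibrationConfig.from_dict,
    "measurement-record/1": MeasurementRecord.from_dict,
    "tps-point/1": TPSReferencePoint.from_dict,
    "plan/1": Plan.from_dict,
    "portal-image/1": PortalImage.from_dict,
    "image-set/1": lambda d: {im["beam_id"]: PortalImage.from_dict(im)
                              for im in d["images"]},
    "poi-set/1": lambda d: [PointOfInterest.from_dict(p) for p in d["pois"]],
    "dose-grid/1": DoseGrid.from_dict,
    "recon/1": ReconstructedDose.from_dict,
    "report/1": DeviationReport.from_dict,
}


def parse_fixture(doc: dict):
    schema = doc.get("schema")
    if schema not in _PARSERS:
        raise FixtureFormatError(f"unknown or missing schema version: {schema!r}")
    return _PARSERS[schema](doc)


def read_fixture(path):
    """Read a fixture file; JSONL files return a list of parsed objects."""
    text = Path(path).read_text().strip()
    if not text:
        raise FixtureFormatError(f"{path}: empty fixture file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        try:
            return [parse_fixture(json.loads(line))
                    for line in text.splitlines() if line.strip()]
        except json.JSONDecodeError as e:
            raise FixtureFormatError(f"{path}: not valid JSON or JSON lines: {e}") from e
    if isinstance(doc, list):
        return [parse_fixture(d) for d in doc]
    # a JSON file may still be one-object-per-line JSONL with a single line
    return parse_fixture(doc)


def image_set_dict(images) -> dict:
    imgs = images.values() if isinstance(images, dict) else images
    return {"schema": "image-set/1", "images": [im.to_dict() for im in imgs]}


def poi_set_dict(pois) -> dict:
    return {"schema": "poi-set/1", "pois": [p.to_dict() for p in pois]}


def write_fixture(obj, path) -> None:
    """Write one fixture (object with ``to_dict``, a prepared dict, or a list
    of record-like objects as JSON lines)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, list):
        lines = [json.dumps(o.to_dict() if hasattr(o, "to_dict") else o)
                 for o in obj]
        path.write_text("\n".join(lines) + "\n")
        return
    doc = obj.to_dict() if hasattr(obj, "to_dict") else obj
    path.write_text(json.dumps(doc, indent=2) + "\n")
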