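"""Best-effort DICOM-RT subset mapping onto the JSON fixture types.

Only the minimal tag sets are read — beam geometry and meterset from an
RT Plan, pixel data + RT Image SID + spacing from an RT Image, dose grid +
scaling from an RT Dose — and unknown/private tags are ignored, which makes
the reader tolerant of vendor-mangled headers.  JSON fixtures remain the
source of truth; writers exist mainly so round trips can be exercised with
synthetic files.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import DicomTagError, FixtureFormatError
from .reconstruction import Beam, DoseGrid, Plan, PortalImage
from .tables import BeamGeometry

RTIMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"
RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"


def _require(ds, name):
    if name not in ds:
        raise DicomTagError(f"required DICOM tag missing: {name}")
    return ds.get(name)


def _new_dataset(sop_class: str, modality: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "PHANTOM^SLAB"
    ds.PatientID = "SYNTH"
    return ds


# ---------------------------------------------------------------------------
# writers (synthetic fixtures)
# ---------------------------------------------------------------------------


def write_rt_image(path, image: PortalImage) -> None:
    ds = _new_dataset(RTIMAGE_STORAGE, "RTIMAGE")
    ds.RTImageLabel = image.beam_id
    ds.RTImageSID = image.sid * 10.0  # mm
    ds.ImagePlanePixelSpacing = [image.spacing_mm, image.spacing_mm]
    px = np.atleast_2d(image.pixels)
    slope = float(px.max()) / 65000.0 if px.max() > 0 else 1.0
    raw = np.round(px / slope).astype(np.uint16)
    ds.Rows, ds.Columns = raw.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = 0.0
    ds.PixelData = raw.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_rt_plan(path, plan: Plan) -> None:
    ds = _new_dataset(RTPLAN_STORAGE, "RTPLAN")
    ds.RTPlanLabel = plan.label
    beam_seq = []
    ref_seq = []
    for n, beam in enumerate(plan.beams, start=1):
        g = beam.geometry
        b = Dataset()
        b.BeamNumber = n
        b.BeamName = beam.beam_id
        b.SourceAxisDistance = g.sad * 10.0
        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.GantryAngle = g.gantry_angle
        jx = Dataset()
        jx.RTBeamLimitingDeviceType = "X"
        jx.LeafJawPositions = [-g.field_x / 2.0 * 10.0, g.field_x / 2.0 * 10.0]
        jy = Dataset()
        jy.RTBeamLimitingDeviceType = "Y"
        jy.LeafJawPositions = [-g.field_y / 2.0 * 10.0, g.field_y / 2.0 * 10.0]
        cp.BeamLimitingDevicePositionSequence = [jx, jy]
        b.ControlPointSequence = [cp]
        beam_seq.append(b)
        rb = Dataset()
        rb.ReferencedBeamNumber = n
        rb.BeamMeterset = g.mu
        ref_seq.append(rb)
    ds.BeamSequence = beam_seq
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = ref_seq
    ds.FractionGroupSequence = [fg]
    ds.save_as(path, enforce_file_format=True)


def write_rt_dose(path, grid: DoseGrid) -> None:
    ds = _new_dataset(RTDOSE_STORAGE, "RTDOSE")
    # DICOM frames are z, rows y, cols x; fixture grid is values[x, y, z]
    vals = np.transpose(grid.values, (2, 1, 0))
    scaling = float(vals.max()) / 4.0e9 if vals.max() > 0 else 1.0
    raw = np.round(vals / scaling).astype(np.uint32)
    ds.DoseGridScaling = scaling
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    ds.NumberOfFrames = raw.shape[0]
    ds.Rows, ds.Columns = raw.shape[1], raw.shape[2]
    ds.PixelSpacing = [grid.spacing[1] * 10.0, grid.spacing[0] * 10.0]
    ds.GridFrameOffsetVector = [i * grid.spacing[2] * 10.0 for i in range(raw.shape[0])]
    ds.ImagePositionPatient = [grid.origin[0] * 10.0, grid.origin[1] * 10.0,
                               grid.origin[2] * 10.0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = raw.tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------


def read_dicom_subset(path, kind: str, *, sid: float = 150.0):
    """Map a minimal DICOM RT file onto the matching fixture object.

    ``kind`` is one of ``rtimage`` (-> PortalImage), ``rtplan`` (-> Plan;
    ``sid`` supplies the imaging distance the plan does not carry), or
    ``rtdose`` (-> DoseGrid, coordinates converted mm -> cm).
    """
    try:
        ds = pydicom.dcmread(path)
    except Exception as e:  # truncated / not DICOM
        raise FixtureFormatError(f"{path}: unreadable DICOM file: {e}") from e

    if kind == "rtimage":
        rt_sid = float(_require(ds, "RTImageSID"))
        spacing = [float(s) for s in _require(ds, "ImagePlanePixelSpacing")]
        _require(ds, "PixelData")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = ds.pixel_array.astype(float) * slope + intercept
        return PortalImage(pixels=pixels, spacing_mm=spacing[0],
                           sid=rt_sid / 10.0,
                           beam_id=str(getattr(ds, "RTImageLabel", "rtimage")))

    if kind == "rtplan":
        beam_seq = _require(ds, "BeamSequence")
        metersets = {}
        for fg in getattr(ds, "FractionGroupSequence", []):
            for rb in getattr(fg, "ReferencedBeamSequence", []):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
        beams = []
        for b in beam_seq:
            cp = _require(b, "ControlPointSequence")[0]
            sad = float(getattr(b, "SourceAxisDistance", 1000.0)) / 10.0
            fx = fy = None
            for jaw in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                pos = [float(p) for p in jaw.LeafJawPositions]
                width = (max(pos) - min(pos)) / 10.0
                if jaw.RTBeamLimitingDeviceType in ("X", "ASYMX"):
                    fx = width
                elif jaw.RTBeamLimitingDeviceType in ("Y", "ASYMY"):
                    fy = width
            if fx is None or fy is None:
                raise DicomTagError(
                    "required DICOM tag missing: BeamLimitingDevicePositionSequence (X/Y jaws)"
                )
            beams.append(Beam(
                beam_id=str(getattr(b, "BeamName", f"beam{b.BeamNumber}")),
                geometry=BeamGeometry(
                    sad=sad, sid=sid, ssd_att=None,
                    gantry_angle=float(_require(cp, "GantryAngle")) % 360.0,
                    field_x=fx, field_y=fy,
                    mu=metersets.get(int(b.BeamNumber), 0.0),
                ),
            ))
        return Plan(label=str(getattr(ds, "RTPlanLabel", "rtplan")), beams=beams)

    if kind == "rtdose":
        _require(ds, "PixelData")
        scaling = float(_require(ds, "DoseGridScaling"))
        spacing = [float(s) for s in _require(ds, "PixelSpacing")]
        ipp = [float(c) for c in _require(ds, "ImagePositionPatient")]
        offsets = [float(o) for o in _require(ds, "GridFrameOffsetVector")]
        vals = ds.pixel_array.astype(float) * scaling
        if vals.ndim == 2:
            vals = vals[None, ...]
        dz = (offsets[1] - offsets[0]) / 10.0 if len(offsets) > 1 else 1.0
        return DoseGrid(
            values=np.transpose(vals, (2, 1, 0)),
            origin=(ipp[0] / 10.0, ipp[1] / 10.0, ipp[2] / 10.0),
            spacing=(spacing[1] / 10.0, spacing[0] / 10.0, dz),
        )

    raise FixtureFormatError(f"unknown DICOM kind '{kind}'")
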