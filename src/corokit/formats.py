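"""Readers and writers for the interchange formats.

Pullbacks travel as multi-frame DICOM (secondary-capture tags) or as 16-bit
PNG series with a JSON sidecar; contours as JSON (per-frame radius arrays)
or cartesian polygon CSV; strut clouds as CSV; label volumes as NIfTI;
centerlines as CSV; meshes as STL/PLY.  All file coordinates are 0-based,
intervals half-open, distances mm.

DICOM spacing is read from the PixelSpacing / SpacingBetweenSlices tags;
when a tag is missing the reader fails naming the tag unless a sidecar JSON
supplies the value (the sidecar wins with a warning).
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .types import Centerline3D, LabelVolume, PolarFrame, RadialContour, StrutPoint

__all__ = [
    "write_pullback_dicom",
    "write_pullback_pngs",
    "read_pullback",
    "write_contours_json",
    "read_contours_json",
    "write_polygon_csv",
    "write_struts_csv",
    "read_struts_csv",
    "write_labels_nifti",
    "read_volume_nifti",
    "write_centerline_csv",
    "read_centerline_csv",
]


# ---------------------------------------------------------------------------
# pullbacks

def write_pullback_dicom(frames: Sequence[PolarFrame], path: str,
                         frame_spacing_mm: float = 0.2) -> None:
    """Write a polar pullback as one multi-frame secondary-capture DICOM."""
    arr = np.stack([f.intensities for f in frames])
    pix = np.round(arr * 65535).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.NumberOfFrames = len(frames)
    ds.Rows, ds.Columns = pix.shape[1], pix.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [str(frames[0].radial_spacing), str(frames[0].radial_spacing)]
    ds.SpacingBetweenSlices = str(frame_spacing_mm)
    ds.ImageComments = json.dumps({"catheter_offset": frames[0].catheter_offset,
                                   "domain": "polar"})
    ds.PixelData = pix.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_pullback_pngs(frames: Sequence[PolarFrame], directory: str,
                        frame_spacing_mm: float = 0.2) -> None:
    """Write a pullback as a 16-bit PNG series plus a JSON sidecar."""
    import imageio.v3 as iio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        pix = np.round(f.intensities * 65535).astype(np.uint16)
        iio.imwrite(d / f"frame_{i:04d}.png", pix)
    sidecar = {"radial_spacing_mm": frames[0].radial_spacing,
               "frame_spacing_mm": frame_spacing_mm,
               "catheter_offset_px": frames[0].catheter_offset}
    (d / "pullback.json").write_text(json.dumps(sidecar, indent=2))


def _load_sidecar(sidecar: Optional[str]) -> dict:
    if sidecar is None:
        return {}
    return json.loads(Path(sidecar).read_text())


def read_pullback(path: str, sidecar: Optional[str] = None) -> tuple:
    """Read a pullback from DICOM or a PNG series directory.

    Returns ``(frames, frame_spacing_mm)``.  Spacing metadata comes from the
    DICOM tags; a missing tag raises naming it, unless the sidecar JSON
    provides the value (which then wins with a warning).
    """
    p = Path(path)
    side = _load_sidecar(sidecar)
    if p.is_dir():
        return _read_pullback_pngs(p, side)

    try:
        ds = pydicom.dcmread(str(p))
        pix = ds.pixel_array
    except Exception as exc:  # truncated / not DICOM
        raise IOError(f"cannot read pullback DICOM: {exc}") from exc

    if "PixelSpacing" in ds:
        spacing = float(ds.PixelSpacing[1])
        if "radial_spacing_mm" in side:
            warnings.warn("sidecar radial_spacing_mm overrides DICOM PixelSpacing")
            spacing = float(side["radial_spacing_mm"])
    elif "radial_spacing_mm" in side:
        warnings.warn("DICOM tag PixelSpacing (0028,0030) missing; using sidecar")
        spacing = float(side["radial_spacing_mm"])
    else:
        raise ValueError("missing spacing metadata: DICOM tag PixelSpacing "
                         "(0028,0030) absent and no sidecar provided")

    if "SpacingBetweenSlices" in ds:
        frame_spacing = float(ds.SpacingBetweenSlices)
    elif "frame_spacing_mm" in side:
        warnings.warn("DICOM tag SpacingBetweenSlices (0018,0088) missing; using sidecar")
        frame_spacing = float(side["frame_spacing_mm"])
    else:
        raise ValueError("missing frame interval: DICOM tag SpacingBetweenSlices "
                         "(0018,0088) absent and no sidecar provided")

    offset = 0
    if "ImageComments" in ds:
        try:
            offset = int(json.loads(ds.ImageComments).get("catheter_offset", 0))
        except (ValueError, TypeError):
            offset = 0
    offset = int(side.get("catheter_offset_px", offset))

    if pix.ndim == 2:
        pix = pix[None]
    frames = [PolarFrame(intensities=pix[i].astype(float) / 65535.0,
                         radial_spacing=spacing, frame_index=i,
                         catheter_offset=offset)
              for i in range(pix.shape[0])]
    return frames, frame_spacing


def _read_pullback_pngs(directory: Path, side_override: dict) -> tuple:
    import imageio.v3 as iio

    side_path = directory / "pullback.json"
    side = json.loads(side_path.read_text()) if side_path.exists() else {}
    side.update(side_override)
    if "radial_spacing_mm" not in side:
        raise ValueError("missing spacing metadata: no radial_spacing_mm in sidecar")
    files = sorted(directory.glob("frame_*.png"))
    if not files:
        raise IOError(f"no frame_*.png files under {directory}")
    frames = []
    for i, f in enumerate(files):
        pix = iio.imread(f).astype(float) / 65535.0
        frames.append(PolarFrame(intensities=pix,
                                 radial_spacing=float(side["radial_spacing_mm"]),
                                 frame_index=i,
                                 catheter_offset=int(side.get("catheter_offset_px", 0))))
    return frames, float(side.get("frame_spacing_mm", 0.2))


# ---------------------------------------------------------------------------
# contours

def write_contours_json(contours: Dict[int, Dict[str, RadialContour]],
                        path: str, radial_spacing: float) -> None:
    """Contours as JSON: per-frame radius arrays, 0-based A-line index."""
    payload = {"radial_spacing_mm": radial_spacing, "frames": {}}
    for f, d in sorted(contours.items()):
        entry = {}
        for kind, c in d.items():
            if c is None:
                continue
            entry[kind] = {"radii_px": [round(float(r), 3) for r in c.radii],
                           "excluded_alines": sorted(int(a) for a in c.excluded_alines)}
        payload["frames"][str(f)] = entry
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path: str) -> tuple:
    payload = json.loads(Path(path).read_text())
    out: Dict[int, Dict[str, RadialContour]] = {}
    for f, entry in payload["frames"].items():
        out[int(f)] = {
            kind: RadialContour(radii=np.asarray(v["radii_px"], dtype=float),
                                kind=kind,
                                excluded_alines=set(v.get("excluded_alines", [])))
            for kind, v in entry.items()}
    return out, float(payload["radial_spacing_mm"])


def write_polygon_csv(polygon_mm: np.ndarray, path: str) -> None:
    """Cartesian polygon CSV (x_mm, y_mm), CCW, first point not repeated."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm"])
        for x, y in np.asarray(polygon_mm, dtype=float):
            w.writerow([f"{x:.6f}", f"{y:.6f}"])


# ---------------------------------------------------------------------------
# struts

def write_struts_csv(struts: Sequence[StrutPoint], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "aline", "depth_px", "x_mm", "y_mm",
                    "cluster", "type", "malapposition_mm"])
        for s in struts:
            w.writerow([s.frame_index, s.aline_index, f"{s.depth_px:.3f}",
                        f"{s.xy_mm[0]:.6f}", f"{s.xy_mm[1]:.6f}",
                        s.cluster_id, s.kind,
                        "" if np.isnan(s.malapposition_mm)
                        else f"{s.malapposition_mm:.4f}"])


def read_struts_csv(path: str) -> List[StrutPoint]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(StrutPoint(
                frame_index=int(row["frame"]), aline_index=int(row["aline"]),
                depth_px=float(row["depth_px"]),
                xy_mm=(float(row["x_mm"]), float(row["y_mm"])),
                cluster_id=int(row["cluster"]), kind=row["type"],
                malapposition_mm=float(row["malapposition_mm"])
                if row["malapposition_mm"] else float("nan")))
    return out


# ---------------------------------------------------------------------------
# volumes / centerlines

def write_labels_nifti(lv: LabelVolume, path: str) -> None:
    affine = np.diag(list(lv.spacing) + [1.0])
    affine[:3, 3] = lv.origin
    nib.save(nib.Nifti1Image(lv.labels.astype(np.uint8), affine), path)


def read_volume_nifti(path: str):
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def write_centerline_csv(cl: Centerline3D, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm", "z_mm", "arclength_mm"])
        for p, s in zip(cl.points, cl.arclength):
            w.writerow([f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", f"{s:.6f}"])


def read_centerline_csv(path: str) -> Centerline3D:
    pts, s = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pts.append([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
            s.append(float(row["arclength_mm"]))
    return Centerline3D(points=np.asarray(pts), arclength=np.asarray(s))
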