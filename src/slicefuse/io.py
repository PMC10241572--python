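"""CT volume and annotation I/O.

Reads single-frame CT DICOM series into :class:`CTVolume` objects (stored
values plus the linear rescale to Hounsfield units), applies display
windowing, and parses rectangular lesion annotations from ImageJ ``.roi``
files or tabular (CSV/JSON) manifests.

Conventions used throughout the package, stated once here:

* pixel coordinates are 0-based with the origin at the top-left;
* boxes are half-open ``(x0, y0, width, height)`` rectangles, so the pixels
  covered are ``[y0, y0+height) x [x0, x0+width)`` — the ImageJ convention;
* slices are ordered ascending by position along the scan axis;
* 8-bit quantization rounds half away from zero.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CTVolume",
    "BoxAnnotation",
    "WindowSpec",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "DEFAULT_LABEL_MAP",
    "read_dicom_series",
    "write_dicom_series",
    "raw_to_hu",
    "hu_to_raw",
    "window_to_uint8",
    "read_imagej_roi",
    "write_imagej_roi",
    "read_annotation_table",
    "write_annotation_table",
]

#: Canonical class names. The positive class is the more prevalent disease
#: (appendicitis in the motivating clinical task); the negative class is the
#: minority disease (diverticulitis).
POSITIVE_LABEL = "positive"
NEGATIVE_LABEL = "negative"

#: Mapping from label strings accepted in annotation tables to canonical labels.
DEFAULT_LABEL_MAP = {
    "positive": POSITIVE_LABEL,
    "negative": NEGATIVE_LABEL,
    "appendicitis": POSITIVE_LABEL,
    "diverticulitis": NEGATIVE_LABEL,
    "tubular": POSITIVE_LABEL,
    "focal": NEGATIVE_LABEL,
}


@dataclass
class CTVolume:
    """An ordered stack of axial CT slices for one patient.

    ``slices`` holds raw stored values (integers as acquired); Hounsfield
    units are obtained through the linear rescale
    ``HU = rescale_slope * stored + rescale_intercept``.
    """

    patient_id: str
    slices: np.ndarray  # (n_slices, rows, cols), integer stored values
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # (row mm/px, col mm/px)
    slice_positions: list[float] = field(default_factory=list)
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("volume needs >= 1 slice of identical shape")
        if not self.slice_positions:
            self.slice_positions = [
                float(i) * self.slice_thickness for i in range(self.n_slices)
            ]
        if len(self.slice_positions) != self.n_slices:
            raise ValueError("slice_positions length mismatch")
        pos = np.asarray(self.slice_positions, dtype=float)
        if self.n_slices > 1 and not np.all(np.diff(np.sort(pos)) > 0):
            raise ValueError("slice positions must be strictly monotone")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.slices.shape[1]), int(self.slices.shape[2])

    def hu(self, index: int) -> np.ndarray:
        """Slice ``index`` converted to Hounsfield units."""
        return raw_to_hu(self.slices[index], self.rescale_slope, self.rescale_intercept)


@dataclass(frozen=True)
class BoxAnnotation:
    """A rectangular lesion ROI on one axial slice, with its class label."""

    patient_id: str
    slice_index: int
    box: tuple[int, int, int, int]  # (x0, y0, width, height), half-open
    label: str

    def __post_init__(self) -> None:
        x0, y0, w, h = self.box
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")
        if w < 1 or h < 1:
            raise ValueError(f"box must have width, height >= 1, got {self.box}")
        if x0 < 0 or y0 < 0:
            raise ValueError(f"box origin must be non-negative, got {self.box}")
        if self.label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"unknown label {self.label!r}")

    def validate_against(self, volume: CTVolume) -> None:
        """Raise if the box or slice index falls outside ``volume``."""
        if self.slice_index >= volume.n_slices:
            raise ValueError("slice_index outside volume")
        rows, cols = volume.shape
        x0, y0, w, h = self.box
        if x0 + w > cols or y0 + h > rows:
            raise ValueError(f"box {self.box} exceeds slice bounds {(rows, cols)}")


@dataclass(frozen=True)
class WindowSpec:
    """A display window: HU interval ``level +- width/2`` mapped to [0, 255].

    Default is the standard abdominal soft-tissue window (level 40 HU,
    width 400 HU).
    """

    level: float = 40.0
    width: float = 400.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


def raw_to_hu(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Linear DICOM rescale: ``HU = slope * stored + intercept``."""
    return np.asarray(stored, dtype=np.float64) * float(slope) + float(intercept)


def hu_to_raw(hu: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Inverse rescale (requires ``slope != 0``); rounds to nearest integer."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return np.rint((np.asarray(hu, dtype=np.float64) - intercept) / slope).astype(np.int32)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def window_to_uint8(hu: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Map HU linearly onto [0, 255] over the window interval, clamping outside."""
    lo = window.level - window.width / 2.0
    scaled = (np.asarray(hu, dtype=np.float64) - lo) / window.width * 255.0
    return _round_half_away(np.clip(scaled, 0.0, 255.0)).astype(np.uint8)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a directory of single-frame CT DICOM files as one volume.

    Slices are sorted ascending by the scan-axis component of
    ImagePositionPatient (falling back to InstanceNumber when positions are
    absent). Mixed SeriesInstanceUIDs, inconsistent slice shapes and
    duplicated positions are rejected.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix != ".csv")
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(p))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")

    series_uids = {str(ds.SeriesInstanceUID) for ds in datasets}
    if len(series_uids) != 1:
        raise ValueError(f"mixed series in {directory}: {sorted(series_uids)}")

    def sort_key(ds: Dataset) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    keys = [sort_key(ds) for ds in datasets]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicated slice positions in series")
    datasets = [ds for _, ds in sorted(zip(keys, datasets), key=lambda t: t[0])]

    arrays = [np.asarray(ds.pixel_array) for ds in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")

    first = datasets[0]
    spacing = first.get("PixelSpacing", [1.0, 1.0])
    return CTVolume(
        patient_id=str(first.get("PatientID", "unknown")),
        slices=np.stack(arrays),
        rescale_slope=float(first.get("RescaleSlope", 1.0)),
        rescale_intercept=float(first.get("RescaleIntercept", 0.0)),
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        slice_positions=[sort_key(ds) for ds in datasets],
        slice_thickness=float(first.get("SliceThickness", 1.0)),
    )


def write_dicom_series(volume: CTVolume, directory: str | Path) -> list[Path]:
    """Write ``volume`` as a minimal single-frame CT series (one file per slice).

    Stored values are written as signed 16-bit integers; the rescale tags are
    carried so that read_dicom_series round-trips the volume exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[volume.patient_id, "series"])
    study_uid = generate_uid(entropy_srcs=[volume.patient_id, "study"])
    paths: list[Path] = []
    for i in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[volume.patient_id, f"slice{i}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.PatientName = volume.patient_id
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.slice_positions[i])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.RescaleSlope = volume.rescale_slope
        ds.RescaleIntercept = volume.rescale_intercept
        ds.Rows, ds.Columns = volume.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = np.ascontiguousarray(volume.slices[i], dtype=np.int16).tobytes()

        path = directory / f"{volume.patient_id}_{i:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# ImageJ .roi rectangles
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_RECT_TYPE = 1


def read_imagej_roi(path: str | Path) -> tuple[int, int, int, int]:
    """Parse a rectangle from an ImageJ ``.roi`` file.

    The format is big-endian: magic ``Iout``, a version short, the ROI type
    byte at offset 6 (1 = rectangle), then top/left/bottom/right shorts at
    offsets 8/10/12/14. Returns ``(x0, y0, width, height)`` with
    ``width = right - left`` and ``height = bottom - top``.
    """
    data = Path(path).read_bytes()
    if len(data) < 16 or data[:4] != _ROI_MAGIC:
        raise ValueError(f"{path}: not an ImageJ .roi file (bad magic)")
    roi_type = data[6]
    if roi_type != _ROI_RECT_TYPE:
        raise ValueError(f"{path}: ROI type {roi_type} is not a rectangle")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    w, h = right - left, bottom - top
    if w < 1 or h < 1:
        raise ValueError(f"{path}: degenerate rectangle {w}x{h}")
    return (left, top, w, h)


def write_imagej_roi(path: str | Path, box: tuple[int, int, int, int]) -> None:
    """Write a minimal ImageJ rectangle ``.roi`` file (for fixtures/export)."""
    x0, y0, w, h = box
    if w < 1 or h < 1:
        raise ValueError("box must have width, height >= 1")
    header = bytearray(64)
    header[:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = _ROI_RECT_TYPE
    struct.pack_into(">4h", header, 8, y0, x0, y0 + h, x0 + w)
    Path(path).write_bytes(bytes(header))


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["patient_id", "slice_index", "x0", "y0", "width", "height", "label"]


def read_annotation_table(
    path: str | Path, label_map: dict[str, str] | None = None
) -> list[BoxAnnotation]:
    """Read box annotations from a CSV or JSON table.

    Expected columns: patient_id, slice_index, x0, y0, width, height, label.
    Label strings are canonicalized through ``label_map``
    (default :data:`DEFAULT_LABEL_MAP`); unknown labels are rejected.
    """
    path = Path(path)
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        raw_label = str(row.label)
        if raw_label not in label_map:
            raise ValueError(f"{path}: unknown label {raw_label!r}")
        out.append(
            BoxAnnotation(
                patient_id=str(row.patient_id),
                slice_index=int(row.slice_index),
                box=(int(row.x0), int(row.y0), int(row.width), int(row.height)),
                label=label_map[raw_label],
            )
        )
    return out


def write_annotation_table(annotations: list[BoxAnnotation], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "patient_id": a.patient_id,
            "slice_index": a.slice_index,
            "x0": a.box[0],
            "y0": a.box[1],
            "width": a.box[2],
            "height": a.box[3],
            "label": a.label,
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        df.to_csv(path, index=False)
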