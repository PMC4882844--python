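"""Image, ROI and mask handling.

Coordinate convention used throughout the package: 0-based ``(row, col)``
with pixel centers at integer coordinates.  A polygon vertex at ``(1.0, 2.0)``
therefore sits exactly on the center of the pixel in row 1, column 2, and the
square pixel occupies ``[row-0.5, row+0.5] x [col-0.5, col+0.5]``.

Mask membership follows the even-odd rule applied to pixel centers, with a
half-open tie-break (top/left edges inclusive): a center lying exactly on a
polygon edge is resolved by testing the point nudged by ``+eps`` in both row
and col, so two polygons sharing an edge never both claim the same pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    DicomReadError,
    EmptyMaskError,
    ImageReadError,
    PolygonError,
)

logger = logging.getLogger(__name__)

LEVELS = ("L1", "L2", "L3", "L4", "L5")
SIDES = ("left", "right")
ROI_KINDS = ("muscle", "fat_reference")
QUARTILES = ("Q1", "Q2", "Q3", "Q4")
QUARTILE_LABELS = QUARTILES + ("Qmean",)

#: nudge applied to pixel centers before the point-in-polygon test; makes the
#: membership rule half-open (top/left inclusive) and partition-safe
_BOUNDARY_EPS = 1e-7


@dataclass(frozen=True)
class AxialSlice:
    """One grayscale axial MRI slice.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in arbitrary scanner units
        (rescale slope/intercept already applied for DICOM input).
    row_spacing_mm, col_spacing_mm
        Physical pixel spacing, millimetres.
    level
        Lumbar level label, one of ``L1``..``L5``.
    subject_id
        Opaque subject identifier.
    patient_left_is_image_right
        True under radiological display convention (the default): the
        patient's left side appears on the viewer's right, i.e. toward
        increasing column index.
    """

    pixels: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    level: str
    subject_id: str = ""
    patient_left_is_image_right: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 16:
            raise ValueError(f"pixel grid must be 2-D and at least 16x16, got {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        if not (self.row_spacing_mm > 0 and self.col_spacing_mm > 0):
            raise ValueError("pixel spacings must be positive")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiPolygon:
    """A labeled closed contour in pixel coordinates.

    ``vertices`` is an ``(m, 2)`` array of ``(row, col)`` coordinates, m >= 3,
    implicitly closed (last vertex joins the first).  The polygon must be
    simple (non-self-intersecting).
    """

    vertices: np.ndarray
    kind: str
    side: str
    level: str
    rater_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise PolygonError(f"need >=3 (row, col) vertices, got array of shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise PolygonError("polygon vertices must be finite")
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {ROI_KINDS}, got {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        object.__setattr__(self, "vertices", v)

    def to_shapely(self) -> _ShapelyPolygon:
        """Shapely polygon in (x=col, y=row) axes; validates simplicity."""
        if len(np.unique(self.vertices, axis=0)) < 3:
            raise PolygonError("polygon has fewer than 3 distinct vertices")
        poly = _ShapelyPolygon(self.vertices[:, ::-1])  # (col, row) -> (x, y)
        if not poly.is_valid or poly.area == 0:
            raise PolygonError("polygon is degenerate or self-intersecting")
        return poly

    def translated(self, drow: float, dcol: float) -> "RoiPolygon":
        return RoiPolygon(
            self.vertices + np.array([drow, dcol]),
            kind=self.kind, side=self.side, level=self.level,
            rater_id=self.rater_id, session_id=self.session_id,
        )


@dataclass(frozen=True)
class RoiMask:
    """Rasterized pixel set of an ROI polygon.

    ``pixels`` is an ``(n, 2)`` integer array of ``(row, col)`` coordinates in
    lexicographic order.  ``source`` keeps the originating polygon for label
    traceability.
    """

    pixels: np.ndarray
    source: RoiPolygon | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise EmptyMaskError("mask must contain at least one (row, col) pixel")
        px = px.astype(np.int64)
        order = np.lexsort((px[:, 1], px[:, 0]))
        object.__setattr__(self, "pixels", px[order])

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


# ---------------------------------------------------------------------------
# image readers
# ---------------------------------------------------------------------------

def read_dicom_slice(path, level: str, subject_id: str | None = None) -> AxialSlice:
    """Read a single-frame grayscale DICOM file into an :class:`AxialSlice`.

    Rescale slope/intercept are applied when present; pixel spacing is taken
    from the PixelSpacing attribute (row spacing first, per the standard).
    The radiological-orientation flag is derived from ImageOrientationPatient
    when present, otherwise defaults to radiological convention with a logged
    warning.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    path = Path(path)
    if not path.exists():
        raise DicomReadError(f"no such file: {path}")
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, Exception) as exc:  # noqa: BLE001 - rewrap all parse failures
        if isinstance(exc, DicomReadError):
            raise
        raise DicomReadError(f"not a readable DICOM file: {path} ({exc})") from exc

    if "PixelData" not in ds:
        raise DicomReadError(f"DICOM file has no pixel data: {path}")
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise DicomReadError(f"multi-frame DICOM not supported: {path}")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise DicomReadError(f"color DICOM not supported: {path}")

    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = slope * arr + intercept

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise DicomReadError(f"DICOM file lacks PixelSpacing: {path}")
    row_sp, col_sp = float(spacing[0]), float(spacing[1])

    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is not None:
        # first direction cosine triplet = direction of increasing column;
        # +X is the patient's left, so patient-left lands on image-right
        # whenever the row cosine has positive X component.
        left_is_right = float(iop[0]) > 0
    else:
        logger.warning(
            "%s: no ImageOrientationPatient; assuming radiological convention", path
        )
        left_is_right = True

    sid = subject_id if subject_id is not None else str(getattr(ds, "PatientID", ""))
    return AxialSlice(
        pixels=arr,
        row_spacing_mm=row_sp,
        col_spacing_mm=col_sp,
        level=level,
        subject_id=sid,
        patient_left_is_image_right=left_is_right,
    )


def read_png_slice(
    path,
    level: str,
    row_spacing_mm: float,
    col_spacing_mm: float,
    subject_id: str = "",
    patient_left_is_image_right: bool = True,
) -> AxialSlice:
    """Read a grayscale (8- or 16-bit) PNG fixture; spacing supplied by caller."""
    from PIL import Image

    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    try:
        img = Image.open(path)
        arr = np.asarray(img)
    except Exception as exc:  # noqa: BLE001
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageReadError(f"expected single-channel grayscale image, got shape {arr.shape}")
    return AxialSlice(
        pixels=arr.astype(float),
        row_spacing_mm=row_spacing_mm,
        col_spacing_mm=col_spacing_mm,
        level=level,
        subject_id=subject_id,
        patient_left_is_image_right=patient_left_is_image_right,
    )


def write_dicom_slice(slice_: AxialSlice, path) -> None:
    """Write an :class:`AxialSlice` as a single-frame MR DICOM file.

    Intensities are rounded to the nearest integer and stored as uint16
    (phantom intensities are integer-valued by construction, so this is
    lossless for package-generated images).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    arr = np.round(slice_.pixels).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PatientID = slice_.subject_id
    ds.SeriesDescription = f"axial T1 {slice_.level}"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [slice_.row_spacing_mm, slice_.col_spacing_mm]
    sign = 1.0 if slice_.patient_left_is_image_right else -1.0
    ds.ImageOrientationPatient = [sign, 0, 0, 0, 1, 0]
    ds.PixelData = arr.tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_polygon(poly: RoiPolygon, grid_rows: int, grid_cols: int) -> RoiMask:
    """Rasterize an ROI polygon to its pixel set on a ``grid_rows x grid_cols`` grid.

    A pixel belongs to the mask iff its center lies inside the polygon by the
    even-odd rule; centers exactly on the boundary are resolved half-open
    (top/left edges inclusive) by nudging the test point ``+eps`` in row and
    col, so polygons sharing an edge partition the plane without overlap.
    """
    v = poly.vertices
    if v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5 \
            or v[:, 0].max() > grid_rows - 0.5 or v[:, 1].max() > grid_cols - 0.5:
        raise PolygonError("polygon extends outside the image grid")
    shp = poly.to_shapely()

    r0 = max(0, int(np.floor(v[:, 0].min())))
    r1 = min(grid_rows - 1, int(np.ceil(v[:, 0].max())))
    c0 = max(0, int(np.floor(v[:, 1].min())))
    c1 = min(grid_cols - 1, int(np.ceil(v[:, 1].max())))
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    inside = shapely.contains_xy(
        shp, cols.ravel() + _BOUNDARY_EPS, rows.ravel() + _BOUNDARY_EPS
    )
    pts = np.column_stack([rows.ravel()[inside], cols.ravel()[inside]])
    if pts.shape[0] == 0:
        raise EmptyMaskError("polygon contains no pixel centers")
    return RoiMask(pixels=pts, source=poly)


# ---------------------------------------------------------------------------
# ROI JSON interchange (schema_version 1)
# ---------------------------------------------------------------------------

ROI_SCHEMA_VERSION = 1


def write_roi_set(rois: list[RoiPolygon], path, subject_id: str = "") -> None:
    """Write one (subject, level, rater, session) ROI set as schema-v1 JSON."""
    import json

    from .errors import RoiSchemaError

    if not rois:
        raise RoiSchemaError("cannot write an empty ROI set")
    levels = {r.level for r in rois}
    raters = {r.rater_id for r in rois}
    sessions = {r.session_id for r in rois}
    if len(levels) != 1 or len(raters) != 1 or len(sessions) != 1:
        raise RoiSchemaError(
            "an ROI set file holds exactly one level/rater/session combination"
        )
    doc = {
        "schema_version": ROI_SCHEMA_VERSION,
        "subject_id": subject_id,
        "level": rois[0].level,
        "rater_id": rois[0].rater_id,
        "session_id": rois[0].session_id,
        "rois": [
            {"kind": r.kind, "side": r.side, "vertices": r.vertices.tolist()}
            for r in rois
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def roi_set_header(path) -> dict:
    """Top-level labels (subject_id, level, rater_id, session_id) of an ROI JSON file."""
    import json

    from .errors import RoiSchemaError

    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise RoiSchemaError(f"{path}: cannot read ROI set ({exc})") from exc
    return {
        "subject_id": doc.get("subject_id", ""),
        "level": doc.get("level"),
        "rater_id": doc.get("rater_id"),
        "session_id": doc.get("session_id"),
    }


def read_roi_set(path, subject_id: str | None = None) -> list[RoiPolygon]:
    """Read a schema-v1 ROI JSON file; schema violations name the offending ROI."""
    import json

    from .errors import RoiSchemaError

    path = Path(path)
    if not path.exists():
        raise RoiSchemaError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RoiSchemaError(f"{path}: not valid JSON ({exc})") from exc

    for key in ("schema_version", "level", "rater_id", "session_id", "rois"):
        if key not in doc:
            raise RoiSchemaError(f"{path}: missing top-level field {key!r}")
    if doc["schema_version"] != ROI_SCHEMA_VERSION:
        raise RoiSchemaError(
            f"{path}: unsupported schema_version {doc['schema_version']!r}"
        )
    if doc["level"] not in LEVELS:
        raise RoiSchemaError(f"{path}: unknown level {doc['level']!r}")

    out: list[RoiPolygon] = []
    for i, entry in enumerate(doc["rois"]):
        for key in ("kind", "side", "vertices"):
            if key not in entry:
                raise RoiSchemaError(f"{path}: roi index {i} missing field {key!r}")
        if entry["kind"] not in ROI_KINDS:
            raise RoiSchemaError(f"{path}: roi index {i} unknown kind {entry['kind']!r}")
        if entry["side"] not in SIDES:
            raise RoiSchemaError(f"{path}: roi index {i} unknown side {entry['side']!r}")
        try:
            poly = RoiPolygon(
                vertices=np.asarray(entry["vertices"], dtype=float),
                kind=entry["kind"],
                side=entry["side"],
                level=doc["level"],
                rater_id=doc["rater_id"],
                session_id=doc["session_id"],
            )
        except (PolygonError, ValueError) as exc:
            raise RoiSchemaError(f"{path}: roi index {i}: {exc}") from exc
        out.append(poly)
    return out
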