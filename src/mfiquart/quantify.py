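"""Normalized muscle fatty infiltration (MFI%) per quartile.

MFI% is the mean T1 signal of a muscle region expressed as a percentage of
the mean signal of a small subcutaneous-fat reference region on the same
slice.  Because it is a ratio of intensities on the same image, any global
linear rescaling of the scanner units cancels.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import EmptyMaskError, MissingRoiError, NormalizationError
from .io import SIDES, AxialSlice, RoiMask, RoiPolygon, rasterize_polygon
from .quartiles import (
    lateral_direction,
    partition_quartiles,
    principal_axis_direction,
)
from .tables import MfiMeasurement

_Q_LABELS = ("Q1", "Q2", "Q3", "Q4")

logger = logging.getLogger(__name__)

#: fat-reference mean below this fraction of the slice maximum triggers a
#: normalization error instead of a division blow-up
FAT_MEAN_EPS_FRACTION = 1e-6


def mean_intensity(slice_: AxialSlice, mask: RoiMask) -> float:
    """Arithmetic mean of the slice intensities at the mask pixels."""
    px = mask.pixels
    rows, cols = slice_.shape
    if px[:, 0].max() >= rows or px[:, 1].max() >= cols or px.min() < 0:
        raise EmptyMaskError("mask extends outside the slice")
    return float(slice_.pixels[px[:, 0], px[:, 1]].mean())


def normalized_mfi(
    slice_: AxialSlice,
    target_mask: RoiMask,
    fat_mask: RoiMask,
    eps_fraction: float = FAT_MEAN_EPS_FRACTION,
) -> float:
    """MFI% of ``target_mask``: 100 x mean(target) / mean(fat reference)."""
    fat_mean = mean_intensity(slice_, fat_mask)
    guard = eps_fraction * float(slice_.pixels.max())
    if fat_mean <= guard:
        raise NormalizationError(
            f"fat reference mean {fat_mean:.3g} is at or below the guard {guard:.3g}"
        )
    return 100.0 * mean_intensity(slice_, target_mask) / fat_mean


def quantify_slice(
    slice_: AxialSlice,
    rois: list[RoiPolygon],
    axis: str = "column",
) -> list[MfiMeasurement]:
    """Measure quartile MFI% for one slice's ROI set (one level/rater/session).

    Per side present: the muscle polygon is rasterized, partitioned into Q1-Q4
    along the medial->lateral axis, and each quartile's MFI% is computed
    against the level's fat reference; Qmean is the unweighted mean of the
    four quartile values.  A complete bilateral level yields 10 measurements.

    Fat-reference laterality: with two fat ROIs each side normalizes to its
    ipsilateral reference; with one, both sides share it.  A missing muscle
    ROI skips that side with a warning; a missing fat reference is an error.
    """
    if axis not in ("column", "principal"):
        raise ValueError(f"axis must be 'column' or 'principal', got {axis!r}")

    muscles = {r.side: r for r in rois if r.kind == "muscle"}
    fats = {r.side: r for r in rois if r.kind == "fat_reference"}
    if not fats:
        raise MissingRoiError(
            f"no fat_reference ROI for level {slice_.level} "
            f"(subject {slice_.subject_id!r})"
        )
    rows, cols = slice_.shape
    fat_masks = {side: rasterize_polygon(p, rows, cols) for side, p in fats.items()}

    out: list[MfiMeasurement] = []
    for side in SIDES:
        if side not in muscles:
            logger.warning(
                "no muscle ROI for side=%s level=%s subject=%s; side skipped",
                side, slice_.level, slice_.subject_id,
            )
            continue
        poly = muscles[side]
        mask = rasterize_polygon(poly, rows, cols)

        fat_mask = fat_masks.get(side) or next(iter(fat_masks.values()))
        if side not in fat_masks:
            logger.info(
                "side=%s level=%s: single fat reference shared across sides",
                side, slice_.level,
            )

        if axis == "principal":
            direction = principal_axis_direction(
                mask, side, slice_.patient_left_is_image_right
            )
        else:
            direction = lateral_direction(side, slice_.patient_left_is_image_right)
        part = partition_quartiles(mask, direction)

        q_values = [
            normalized_mfi(slice_, RoiMask(q, source=poly), fat_mask)
            for q in part.quartiles
        ]
        for label, value in zip(_Q_LABELS, q_values):
            out.append(_measurement(slice_, poly, label, value))
        out.append(_measurement(slice_, poly, "Qmean", float(np.mean(q_values))))
    return out


def whole_roi_mfi(
    slice_: AxialSlice, rois: list[RoiPolygon]
) -> dict[str, float]:
    """Diagnostic whole-ROI MFI% per side (no quartiling).

    Equals Qmean exactly when the mask size is a multiple of 4; otherwise
    differs by at most the contribution of the remainder pixels.
    """
    muscles = {r.side: r for r in rois if r.kind == "muscle"}
    fats = {r.side: r for r in rois if r.kind == "fat_reference"}
    if not fats:
        raise MissingRoiError(f"no fat_reference ROI for level {slice_.level}")
    rows, cols = slice_.shape
    fat_masks = {side: rasterize_polygon(p, rows, cols) for side, p in fats.items()}
    out = {}
    for side, poly in muscles.items():
        mask = rasterize_polygon(poly, rows, cols)
        fat_mask = fat_masks.get(side) or next(iter(fat_masks.values()))
        out[side] = normalized_mfi(slice_, mask, fat_mask)
    return out


def _measurement(slice_, poly, quartile, value) -> MfiMeasurement:
    return MfiMeasurement(
        subject_id=slice_.subject_id,
        level=slice_.level,
        side=poly.side,
        quartile=quartile,
        rater_id=poly.rater_id,
        session_id=poly.session_id,
        mfi_percent=value,
    )
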