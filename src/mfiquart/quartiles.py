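"""Medial-to-lateral quartile partition of a muscle ROI.

The partition is defined on pixel counts, not geometric width: pixels are
ordered by their scalar projection onto a medial->lateral axis and cut into
four contiguous blocks whose sizes differ by at most one pixel.  Q1 is the
most medial block, Q4 the most lateral.

The medial->lateral axis is, by default, the in-plane image-column axis
signed per side: on an axial lumbar slice the paravertebral muscles flank
the midline horizontally, so "away from the midline" is a column direction
whose sign depends on the side and on the display convention.  An
alternative axis (the mask's first principal component, sign-aligned to the
column axis) is available for sensitivity analysis; which convention
produced an output is recorded by callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError
from .io import RoiMask

AXIS_CONVENTIONS = ("column", "principal")


def lateral_direction(side: str, patient_left_is_image_right: bool = True) -> np.ndarray:
    """Unit (row, col) vector pointing medial->lateral for the given side.

    Under radiological convention (``patient_left_is_image_right=True``) the
    patient's right side lies on image-left, so lateral for ``side="right"``
    is toward decreasing column index, ``(0, -1)``; for ``side="left"`` it is
    ``(0, +1)``.  Flipping the convention flag negates both.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    sign = 1.0 if side == "left" else -1.0
    if not patient_left_is_image_right:
        sign = -sign
    return np.array([0.0, sign])


def principal_axis_direction(
    mask: RoiMask, side: str, patient_left_is_image_right: bool = True
) -> np.ndarray:
    """First principal axis of the mask's pixel coordinates, as a unit
    (row, col) vector sign-aligned with the column-axis lateral direction."""
    coords = mask.pixels.astype(float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    ref = lateral_direction(side, patient_left_is_image_right)
    if float(axis @ ref) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass(frozen=True)
class QuartilePartition:
    """Four disjoint, exhaustive pixel blocks of a muscle mask, medial->lateral.

    ``quartiles[0]`` is Q1 (most medial) ... ``quartiles[3]`` is Q4 (most
    lateral); each is an ``(n_i, 2)`` integer array of (row, col) pixels.
    """

    quartiles: tuple
    side: str | None
    axis_direction: np.ndarray
    source_mask: RoiMask

    def __post_init__(self) -> None:
        if len(self.quartiles) != 4:
            raise ValueError("a partition has exactly 4 blocks")
        sizes = self.sizes
        if min(sizes) == 0:
            raise ValueError("every quartile must be non-empty")
        if max(sizes) - min(sizes) > 1:
            raise ValueError("quartile sizes must differ by at most 1 pixel")
        total = sum(sizes)
        if total != len(self.source_mask):
            raise ValueError("quartiles must exactly tile the source mask")

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return tuple(int(q.shape[0]) for q in self.quartiles)

    def label_array(self, shape: tuple[int, int]) -> np.ndarray:
        """Integer label image: 0 = background, 1..4 = Q1..Q4 (QA overlays)."""
        lab = np.zeros(shape, dtype=np.uint8)
        for i, q in enumerate(self.quartiles, start=1):
            lab[q[:, 0], q[:, 1]] = i
        return lab


def partition_quartiles(mask: RoiMask, direction: np.ndarray) -> QuartilePartition:
    """Split ``mask`` into 4 equal-pixel-count blocks along ``direction``.

    Every pixel receives the scalar projection of its (row, col) coordinate
    onto ``direction``; pixels are sorted ascending by projection with a
    deterministic tie-break (then row, then col) and the sorted sequence is
    cut into four contiguous blocks of size ``floor(N/4)`` or ``ceil(N/4)``,
    the ``N mod 4`` larger blocks placed first (medial first).
    """
    coords = mask.pixels
    n = coords.shape[0]
    if n < 4:
        raise EmptyMaskError(f"quartiling requires at least 4 pixels, mask has {n}")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    proj = coords.astype(float) @ direction
    order = np.lexsort((coords[:, 1], coords[:, 0], proj))
    ranked = coords[order]

    base, rem = divmod(n, 4)
    sizes = [base + 1 if i < rem else base for i in range(4)]
    bounds = np.cumsum([0] + sizes)
    blocks = tuple(ranked[bounds[i]:bounds[i + 1]] for i in range(4))

    side = mask.source.side if mask.source is not None else None
    return QuartilePartition(
        quartiles=blocks, side=side, axis_direction=direction, source_mask=mask
    )
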