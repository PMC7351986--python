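"""Medial-to-lateral quartile partitioning of muscle ROI cross-sections.

Each per-slice, per-side ROI of the deep cervical extensor compartment is cut
into four contiguous bins along the medial-lateral axis: Q1 abuts the spinous
process (the per-slice midline landmark), Q4 is most lateral. The
medial-lateral coordinate of a voxel is its unsigned image-column distance
from the landmark column, so mirrored left/right masks receive identical
coordinates.

Two partition rules are available:

``area`` (default)
    Equal voxel counts: voxels are sorted by (coordinate, row, column) and cut
    into four rank bins whose sizes differ pairwise by at most one, larger
    bins placed medially first. Per-quartile means are then equally precise.
``width``
    Equal-width bands of the coordinate range; bin populations may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Side = Literal["left", "right"]
SIDES: tuple[Side, Side] = ("left", "right")

#: Integer codes used in mask volumes.
SIDE_CODES = {"left": 1, "right": 2}


class EmptyROIError(ValueError):
    """The region of interest contains no voxels."""


class LandmarkSideError(ValueError):
    """ROI voxels lie on the wrong side of (or straddle) the landmark column."""


@dataclass
class MuscleMask:
    """Bilateral deep-extensor ROIs plus a per-slice midline landmark.

    ``rois`` is an integer volume ``(slice, row, column)`` with 0 background,
    1 left-side ROI, 2 right-side ROI ("right" = increasing column index).
    ``landmark_columns`` gives the spinous-process midline column per slice.
    """

    rois: np.ndarray
    landmark_columns: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.rois = np.asarray(self.rois)
        self.landmark_columns = np.asarray(self.landmark_columns, dtype=int)
        if self.rois.ndim != 3:
            raise ValueError("rois must be a (slice, row, column) volume")
        if self.landmark_columns.shape != (self.rois.shape[0],):
            raise ValueError("need one landmark column per slice")

    @property
    def n_slices(self) -> int:
        return self.rois.shape[0]

    def side_roi(self, slice_index: int, side: Side) -> np.ndarray:
        """Boolean ROI of one side on one slice."""
        return self.rois[slice_index] == SIDE_CODES[side]


def medial_lateral_coordinate(
    roi: np.ndarray, landmark_column: int, side: Side
) -> np.ndarray:
    """Per-voxel medial-lateral coordinate for one side's ROI on one slice.

    The coordinate is the unsigned column distance from the landmark column
    and increases laterally on both sides. Voxels are enumerated in row-major
    order (the order of ``np.nonzero``).

    Raises
    ------
    EmptyROIError
        If the ROI has no voxels.
    LandmarkSideError
        If any ROI voxel lies strictly on the wrong side of the landmark
        (mask and landmark are mutually inconsistent).
    """
    roi = np.asarray(roi, dtype=bool)
    rows, cols = np.nonzero(roi)
    if rows.size == 0:
        raise EmptyROIError("ROI is empty")
    if side == "right":
        if (cols < landmark_column).any():
            raise LandmarkSideError("right-side ROI has voxels medial of the landmark column")
    elif side == "left":
        if (cols > landmark_column).any():
            raise LandmarkSideError("left-side ROI has voxels medial of the landmark column")
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return np.abs(cols - landmark_column).astype(float)


def _quartile_sizes(n: int) -> list[int]:
    """Bin sizes for n voxels: ceil(n/4) for the first n % 4 bins (medial first)."""
    base, rem = divmod(n, 4)
    return [base + 1] * rem + [base] * (4 - rem)


def partition_quartiles(
    roi: np.ndarray,
    coordinates: np.ndarray,
    rule: Literal["area", "width"] = "area",
) -> np.ndarray:
    """Partition one slice-side ROI into quartile labels 1-4 (medial -> lateral).

    Parameters
    ----------
    roi : boolean slice array.
    coordinates : medial-lateral coordinate per ROI voxel, in ``np.nonzero``
        order (as returned by :func:`medial_lateral_coordinate`).
    rule : ``"area"`` for equal voxel counts (ties broken by row then column,
        larger remainder bins medial), ``"width"`` for equal coordinate bands.

    Returns
    -------
    numpy.ndarray
        Integer array on the slice grid; 0 outside the ROI, 1-4 inside.
    """
    roi = np.asarray(roi, dtype=bool)
    rows, cols = np.nonzero(roi)
    if rows.size == 0:
        raise EmptyROIError("ROI is empty")
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != rows.shape:
        raise ValueError("one coordinate per ROI voxel required")

    labels = np.zeros(roi.shape, dtype=np.int8)
    if rule == "area":
        order = np.lexsort((cols, rows, coordinates))
        bounds = np.cumsum(_quartile_sizes(rows.size))
        start = 0
        for q, stop in enumerate(bounds, start=1):
            sel = order[start:stop]
            labels[rows[sel], cols[sel]] = q
            start = stop
    elif rule == "width":
        cmin, cmax = coordinates.min(), coordinates.max()
        if cmax == cmin:
            q = np.ones(rows.size, dtype=np.int8)
        else:
            q = np.minimum(
                (4 * (coordinates - cmin) / (cmax - cmin)).astype(int) + 1, 4
            ).astype(np.int8)
        labels[rows, cols] = q
    else:
        raise ValueError(f"unknown quartile rule {rule!r}")
    return labels


def partition_volume(
    mask: MuscleMask, rule: Literal["area", "width"] = "area"
) -> tuple[np.ndarray, list[tuple[int, Side]]]:
    """Partition every slice and side of a mask volume independently.

    Returns
    -------
    (labels, missing)
        ``labels`` is an int8 volume with quartile codes 1-4 inside either
        side's ROI (sides stay distinguishable through the mask itself).
        ``missing`` lists ``(slice_index, side)`` pairs whose ROI was empty;
        an empty slice-side is recorded, never fatal.
    """
    labels = np.zeros(mask.rois.shape, dtype=np.int8)
    missing: list[tuple[int, Side]] = []
    for s in range(mask.n_slices):
        for side in SIDES:
            roi = mask.side_roi(s, side)
            if not roi.any():
                missing.append((s, side))
                continue
            coords = medial_lateral_coordinate(roi, int(mask.landmark_columns[s]), side)
            labels[s] = np.where(roi, partition_quartiles(roi, coords, rule=rule), labels[s])
    return labels, missing
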