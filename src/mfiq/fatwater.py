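"""Voxelwise muscle fat infiltration (MFI) maps from fat/water image pairs.

MFI is the pure signal ratio ``100 * I_F / (I_F + I_W)`` computed per voxel
from already-separated fat (I_F) and water (I_W) images (2-point Dixon).
Being a ratio it is invariant to any common intensity scaling, so no bias-field
or normalisation step is applied. Voxels with zero total signal carry no
measurement and are flagged invalid rather than set to 0 or 100; invalid
voxels are excluded from every downstream mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEVELS = ("C4", "C5", "C6", "C7")


class InputShapeError(ValueError):
    """Fat and water arrays do not share one voxel grid."""


class NoMeasurableTissueError(ValueError):
    """A requested mean has no valid voxels: no signal, not zero fat."""


@dataclass
class FatWaterVolume:
    """Paired fat/water intensity volumes on a common grid.

    Arrays are indexed ``(slice, row, column)``; axial slices are along axis 0.
    ``levels`` maps each vertebral level (C4-C7, or a subset) to an inclusive
    ``(first_slice, last_slice)`` range; ranges must be disjoint and at least
    three slices wide so a central-3 average is always available.
    """

    fat: np.ndarray
    water: np.ndarray
    levels: dict[str, tuple[int, int]]
    voxel_size: tuple[float, float, float] = (3.0, 0.7, 0.7)  # mm (slice, row, col)
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.fat = np.asarray(self.fat, dtype=float)
        self.water = np.asarray(self.water, dtype=float)
        if self.fat.shape != self.water.shape:
            raise InputShapeError(
                f"fat {self.fat.shape} and water {self.water.shape} shapes differ"
            )
        if (self.fat < 0).any() or (self.water < 0).any():
            raise ValueError("intensities must be non-negative")
        n_slices = self.fat.shape[self.slice_axis]
        spans: list[tuple[int, int]] = []
        for level, (lo, hi) in self.levels.items():
            if not 0 <= lo <= hi < n_slices:
                raise ValueError(f"level {level} range ({lo}, {hi}) outside 0..{n_slices - 1}")
            if hi - lo + 1 < 3:
                raise ValueError(f"level {level} spans {hi - lo + 1} slices; need >= 3")
            spans.append((lo, hi))
        spans.sort()
        for (_, h1), (l2, _) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError("level slice ranges overlap")

    @property
    def n_slices(self) -> int:
        return self.fat.shape[self.slice_axis]


@dataclass
class MFIMap:
    """Per-voxel MFI in percent with a validity flag.

    ``values`` is meaningful only where ``valid`` is True (I_F + I_W > 0);
    invalid entries are stored as NaN so accidental use is loud.
    """

    values: np.ndarray
    valid: np.ndarray = field(repr=False)


def compute_mfi_map(volume: FatWaterVolume) -> MFIMap:
    """Compute the voxelwise MFI map ``100 * I_F / (I_F + I_W)``.

    Voxels whose total signal is zero are flagged invalid (NaN value);
    every valid voxel lies in [0, 100] for non-negative inputs.
    """
    total = volume.fat + volume.water
    valid = total > 0
    values = np.full(volume.fat.shape, np.nan, dtype=float)
    np.divide(100.0 * volume.fat, total, out=values, where=valid)
    return MFIMap(values=values, valid=valid)


def masked_mean(mfi: MFIMap, selection: np.ndarray) -> float:
    """Arithmetic mean of valid MFI values over a voxel selection.

    Parameters
    ----------
    mfi : MFIMap
    selection : boolean array on the map grid (or integer index tuple).

    Raises
    ------
    NoMeasurableTissueError
        If the selection is empty or contains no valid voxel — distinct from
        a genuine 0 % measurement.
    """
    selection = np.asarray(selection)
    if selection.dtype == bool:
        if selection.shape != mfi.values.shape:
            raise InputShapeError("selection mask shape differs from MFI map")
        use = selection & mfi.valid
        vals = mfi.values[use]
    else:  # integer voxel indices, shape (n, ndim)
        idx = tuple(selection.T)
        vals = mfi.values[idx]
        vals = vals[mfi.valid[idx]]
    if vals.size == 0:
        raise NoMeasurableTissueError("no valid voxels in selection")
    return float(vals.mean())
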