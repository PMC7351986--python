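"""Reduction of voxel maps to the analysis table: MFI per participant x level x quartile.

Per vertebral level, MFI is averaged over the three slices centred on the
level's annotated slice range (the central slices are least affected by
level-boundary ambiguity). Bilateral handling defaults to pooling left+right
voxels before averaging, which weights by measured tissue; averaging the two
side means is available as an alternative.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from mfiq.fatwater import LEVELS, FatWaterVolume, MFIMap
from mfiq.quartiles import SIDE_CODES, SIDES, MuscleMask

QUARTILES = (1, 2, 3, 4)

#: Columns of the tidy analysis table (one row per participant x level x quartile).
TABLE_COLUMNS = (
    "participant_id",
    "level",
    "quartile",
    "mfi",
    "n_voxels",
    "age",
    "sex",
    "bmi",
    "ndi_percent",
    "group",
)


class JoinError(KeyError):
    """Analysis records reference participants absent from the metadata table."""


def slices_for_level(volume: FatWaterVolume, level: str) -> tuple[int, int, int]:
    """The three slices used for a level: the range's midpoint slice +/- 1.

    Deterministic; requires the annotated range to span at least three slices.
    """
    if level not in volume.levels:
        raise KeyError(f"volume has no slice annotation for level {level}")
    lo, hi = volume.levels[level]
    if hi - lo + 1 < 3:
        raise ValueError(f"level {level} range ({lo}, {hi}) has fewer than 3 slices")
    mid = (lo + hi) // 2
    return (mid - 1, mid, mid + 1)


def quartile_level_mfi(
    mfi: MFIMap,
    mask: MuscleMask,
    labels: np.ndarray,
    volume: FatWaterVolume,
    participant_id: str,
    bilateral: Literal["pool", "side-mean"] = "pool",
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-level, per-quartile MFI for one participant.

    For each (level, quartile) cell, all valid voxels carrying that quartile
    label across the level's three selected slices and both sides are pooled
    and averaged (``bilateral="pool"``), or each side is averaged first and
    the two side means averaged (``"side-mean"``).

    Returns
    -------
    (records, missing)
        ``records`` has one row per measurable cell; ``missing`` logs cells
        with zero valid voxels.
    """
    if labels.shape != mfi.values.shape or mask.rois.shape != mfi.values.shape:
        raise ValueError("MFI map, mask and quartile labels must share one grid")

    rows: list[dict] = []
    missing: list[dict] = []
    for level in volume.levels:
        sl = list(slices_for_level(volume, level))
        for q in QUARTILES:
            side_vals = {}
            for side in SIDES:
                sel = (
                    (labels[sl] == q)
                    & (mask.rois[sl] == SIDE_CODES[side])
                    & mfi.valid[sl]
                )
                vals = mfi.values[sl][sel]
                if vals.size:
                    side_vals[side] = (vals.sum(), vals.size)
            n_vox = sum(n for _, n in side_vals.values())
            if n_vox == 0:
                missing.append({"participant_id": participant_id, "level": level, "quartile": q})
                continue
            if bilateral == "pool":
                value = sum(s for s, _ in side_vals.values()) / n_vox
            elif bilateral == "side-mean":
                value = float(np.mean([s / n for s, n in side_vals.values()]))
            else:
                raise ValueError(f"unknown bilateral rule {bilateral!r}")
            rows.append(
                {
                    "participant_id": participant_id,
                    "level": level,
                    "quartile": q,
                    "mfi": float(value),
                    "n_voxels": int(n_vox),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "level", "quartile", "mfi", "n_voxels"]), missing


def build_analysis_table(records: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Join MFI records with participant metadata into the long analysis table.

    One row per (participant, level, quartile) with age, sex, BMI, NDI and
    recovery group attached; missing cells simply yield no row (mixed models
    tolerate unbalanced data; nothing is imputed).
    """
    if records.empty:
        raise ValueError("no MFI records to tabulate")
    meta_cols = ["participant_id", "age", "sex", "bmi", "ndi_percent", "group"]
    missing_meta = set(records["participant_id"]) - set(participants["participant_id"])
    if missing_meta:
        raise JoinError(f"records reference unknown participants: {sorted(missing_meta)}")
    table = records.merge(participants[meta_cols], on="participant_id", how="left")
    return table[list(TABLE_COLUMNS)]


def expected_row_count(n_participants: int, n_levels: int = len(LEVELS)) -> int:
    """Row count of a complete table: participants x levels x 4 quartiles."""
    return n_participants * n_levels * len(QUARTILES)
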