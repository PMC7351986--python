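"""NIfTI / CSV / JSON input-output and dataset manifests.

Volumes are stored as NIfTI with array axes (slice, row, column) and a
diagonal affine built from the voxel size. Slice-level annotations that NIfTI
cannot carry (vertebral-level slice ranges, per-slice spinous-process landmark
columns, the mask label scheme) travel in a JSON sidecar next to the volumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from mfiq.fatwater import LEVELS, FatWaterVolume
from mfiq.quartiles import SIDE_CODES, MuscleMask

REQUIRED_LEVELS = LEVELS


class VolumeCompatibilityError(ValueError):
    """Two volumes expected on one grid have different shapes or affines."""


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_nifti(array: np.ndarray, path: str | Path,
                voxel_size: tuple[float, float, float] = (3.0, 0.7, 0.7)) -> Path:
    """Write an array volume as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_annotations(path: str | Path, levels: dict[str, tuple[int, int]],
                      landmark_columns: np.ndarray) -> Path:
    payload = {
        "levels": {k: [int(a), int(b)] for k, (a, b) in levels.items()},
        "landmark_columns": [int(c) for c in landmark_columns],
        "mask_labels": dict(SIDE_CODES),
        "axes": ["slice", "row", "column"],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_annotations(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    missing = [lv for lv in REQUIRED_LEVELS if lv not in payload.get("levels", {})]
    if missing:
        raise ValueError(
            f"annotation file {path} lacks slice ranges for levels {missing}; "
            f"required levels are {list(REQUIRED_LEVELS)}"
        )
    return payload


def read_fatwater(fat_path: str | Path, water_path: str | Path,
                  annotations_path: str | Path) -> FatWaterVolume:
    """Load a fat/water pair plus its annotation sidecar, verifying grid compatibility."""
    fat, fat_aff = read_nifti(fat_path)
    water, water_aff = read_nifti(water_path)
    if fat.shape != water.shape or not np.allclose(fat_aff, water_aff):
        raise VolumeCompatibilityError(
            f"fat volume {fat_path} and water volume {water_path} are not on one grid "
            f"(shapes {fat.shape} vs {water.shape})"
        )
    ann = read_annotations(annotations_path)
    levels = {k: (v[0], v[1]) for k, v in ann["levels"].items()}
    voxel_size = tuple(np.abs(np.diag(fat_aff)[:3]))
    return FatWaterVolume(fat=fat, water=water, levels=levels, voxel_size=voxel_size)


def read_mask(mask_path: str | Path, annotations_path: str | Path,
              reference: FatWaterVolume | None = None) -> MuscleMask:
    """Load a labelled mask volume; optionally verify it shares the reference grid."""
    rois, aff = read_nifti(mask_path)
    ann = read_annotations(annotations_path)
    if reference is not None and rois.shape != reference.fat.shape:
        raise VolumeCompatibilityError(
            f"mask {mask_path} grid {rois.shape} differs from image grid {reference.fat.shape}"
        )
    return MuscleMask(rois=np.asarray(rois, dtype=np.int8),
                      landmark_columns=np.asarray(ann["landmark_columns"]))


def config_hash(config: dict) -> str:
    """Stable short hash of an effective configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, seed: int, config: dict, files: list[str]) -> Path:
    path = Path(path)
    payload = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "files": sorted(files),
    }
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def write_dataset(dataset, out_dir: str | Path, config: dict | None = None) -> dict[str, Path]:
    """Write a synthetic cohort to disk: NIfTI volumes, CSV tables, manifest.

    Layout: ``<out>/volumes/<pid>_{fat,water,mask}.nii.gz``, one shared
    ``annotations.json``, ``metadata.csv``, ``ground_truth_cells.csv``,
    ``ground_truth_random_effects.csv`` and ``manifest.json``.
    """
    from mfiq.synthetic import participants_to_frame

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    first = dataset.imaging[0]
    files["annotations"] = write_annotations(
        out / "annotations.json", first.volume.levels, first.mask.landmark_columns
    )
    for img in dataset.imaging:
        pid = img.participant.id
        vx = img.volume.voxel_size
        files[f"{pid}_fat"] = write_nifti(img.volume.fat, out / "volumes" / f"{pid}_fat.nii.gz", vx)
        files[f"{pid}_water"] = write_nifti(img.volume.water, out / "volumes" / f"{pid}_water.nii.gz", vx)
        files[f"{pid}_mask"] = write_nifti(img.mask.rois, out / "volumes" / f"{pid}_mask.nii.gz", vx)

    meta = participants_to_frame(dataset.participants)
    files["metadata"] = out / "metadata.csv"
    meta.to_csv(files["metadata"], index=False)
    files["ground_truth_cells"] = out / "ground_truth_cells.csv"
    dataset.ground_truth.cells.to_csv(files["ground_truth_cells"], index=False)
    files["ground_truth_random_effects"] = out / "ground_truth_random_effects.csv"
    dataset.ground_truth.random_effects.to_csv(files["ground_truth_random_effects"], index=False)

    files["manifest"] = write_manifest(
        out / "manifest.json", dataset.seed, config or {},
        [str(p.relative_to(out)) for p in files.values()],
    )
    return files
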