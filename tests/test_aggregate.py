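"""Slice selection and reduction to the participant x level x quartile table."""

import numpy as np
import pandas as pd
import pytest

from mfiq.aggregate import (
    JoinError,
    build_analysis_table,
    expected_row_count,
    quartile_level_mfi,
    slices_for_level,
)
from mfiq.fatwater import FatWaterVolume, compute_mfi_map
from mfiq.quartiles import MuscleMask, partition_volume


def _vol(fat, water, levels):
    return FatWaterVolume(fat=fat, water=water, levels=levels)


def _symmetric_mask(n_slices, n_rows=10, n_cols=31, landmark=15):
    rois = np.zeros((n_slices, n_rows, n_cols), dtype=np.int8)
    rois[:, 2:8, 3:15] = 1
    rois[:, 2:8, 16:28] = 2
    return MuscleMask(rois=rois, landmark_columns=np.full(n_slices, landmark))


class TestSliceSelection:
    def test_midpoint_rule(self):
        vol = _vol(np.ones((10, 2, 2)), np.ones((10, 2, 2)), {"C4": (4, 9)})
        assert slices_for_level(vol, "C4") == (5, 6, 7)

    def test_exact_three_slices_forced(self):
        vol = _vol(np.ones((5, 2, 2)), np.ones((5, 2, 2)), {"C4": (2, 4)})
        assert slices_for_level(vol, "C4") == (2, 3, 4)

    def test_short_range_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _vol(np.ones((2, 2, 2)), np.ones((2, 2, 2)), {"C4": (0, 1)})


class TestQuartileLevelMFI:
    def _setup(self, fat_value=30.0, water_value=70.0, n_slices=12):
        mask = _symmetric_mask(n_slices)
        shape = mask.rois.shape
        fat = np.full(shape, float(fat_value))
        water = np.full(shape, float(water_value))
        levels = {lv: (3 * i, 3 * i + 2) for i, lv in enumerate(("C4", "C5", "C6", "C7"))}
        vol = _vol(fat, water, levels)
        labels, _ = partition_volume(mask)
        return vol, mask, labels

    def test_uniform_field(self):
        vol, mask, labels = self._setup(30.0, 70.0)
        recs, missing = quartile_level_mfi(compute_mfi_map(vol), mask, labels, vol, "p0")
        assert not missing
        assert len(recs) == 16
        np.testing.assert_allclose(recs["mfi"], 30.0)
        assert (recs["n_voxels"] > 0).all()

    def test_balanced_three_slice_mean(self):
        vol, mask, labels = self._setup()
        # per-slice MFI 10 / 20 / 30 within level C4 (slices 0-2), equal counts
        for s, m in zip((0, 1, 2), (10.0, 20.0, 30.0)):
            vol.fat[s] = m
            vol.water[s] = 100.0 - m
        recs, _ = quartile_level_mfi(compute_mfi_map(vol), mask, labels, vol, "p0")
        c4 = recs[recs["level"] == "C4"]
        np.testing.assert_allclose(c4["mfi"], 20.0)

    def test_against_per_voxel_pooling_oracle(self):
        rng = np.random.default_rng(77)
        vol, mask, labels = self._setup()
        vol.fat[:] = rng.uniform(0, 100, vol.fat.shape)
        vol.water[:] = rng.uniform(1, 100, vol.water.shape)
        mfi = compute_mfi_map(vol)
        recs, _ = quartile_level_mfi(mfi, mask, labels, vol, "p0")
        for row in recs.itertuples():
            lo, hi = vol.levels[row.level]
            mid = (lo + hi) // 2
            vals = []
            for s in (mid - 1, mid, mid + 1):
                for r in range(vol.fat.shape[1]):
                    for c in range(vol.fat.shape[2]):
                        if labels[s, r, c] == row.quartile and mask.rois[s, r, c] > 0:
                            vals.append(100 * vol.fat[s, r, c] /
                                        (vol.fat[s, r, c] + vol.water[s, r, c]))
            assert row.mfi == pytest.approx(np.mean(vals), abs=1e-9)
            assert row.n_voxels == len(vals)

    def test_pooling_identity(self):
        """Pooled mean equals the voxel-count-weighted mean of per-side means."""
        rng = np.random.default_rng(8)
        vol, mask, labels = self._setup()
        vol.fat[:] = rng.uniform(0, 100, vol.fat.shape)
        vol.water[:] = rng.uniform(1, 100, vol.water.shape)
        mfi = compute_mfi_map(vol)
        pooled, _ = quartile_level_mfi(mfi, mask, labels, vol, "p0", bilateral="pool")
        for row in pooled.itertuples():
            lo, hi = vol.levels[row.level]
            mid = (lo + hi) // 2
            sl = [mid - 1, mid, mid + 1]
            weighted, n_total = 0.0, 0
            for side_code in (1, 2):
                sel = (labels[sl] == row.quartile) & (mask.rois[sl] == side_code)
                vals = mfi.values[sl][sel]
                weighted += vals.sum()
                n_total += vals.size
            assert row.mfi == pytest.approx(weighted / n_total, abs=1e-9)

    def test_bilateral_symmetry_on_mirror_phantom(self):
        """On a mirror-symmetric phantom, dropping either side changes no record."""
        rng = np.random.default_rng(9)
        vol, mask, labels = self._setup()
        half = rng.uniform(0, 100, (12, 10, 15))
        vol.fat[:, :, :15] = half
        vol.fat[:, :, 16:] = half[:, :, ::-1]
        vol.fat[:, :, 15] = 50.0
        vol.water[:] = 100.0 - vol.fat
        mfi = compute_mfi_map(vol)
        full, _ = quartile_level_mfi(mfi, mask, labels, vol, "p0")
        for side_keep in (1, 2):
            one_sided = MuscleMask(
                rois=np.where(mask.rois == side_keep, mask.rois, 0),
                landmark_columns=mask.landmark_columns,
            )
            labels_one, _ = partition_volume(one_sided)
            recs, _ = quartile_level_mfi(mfi, one_sided, labels_one, vol, "p0")
            merged = full.merge(recs, on=["level", "quartile"], suffixes=("_full", "_one"))
            np.testing.assert_allclose(merged["mfi_full"], merged["mfi_one"], atol=1e-9)

    def test_missing_cell_logged(self):
        vol, mask, labels = self._setup()
        vol.fat[0:3] = 0.0
        vol.water[0:3] = 0.0  # C4 entirely invalid
        recs, missing = quartile_level_mfi(compute_mfi_map(vol), mask, labels, vol, "p0")
        assert len(recs) == 12
        assert len(missing) == 4
        assert {m["level"] for m in missing} == {"C4"}


class TestAnalysisTable:
    def _records(self, participants, n_levels=4):
        rows = []
        for pid in participants["participant_id"]:
            for lv in ("C4", "C5", "C6", "C7")[:n_levels]:
                for q in (1, 2, 3, 4):
                    rows.append({"participant_id": pid, "level": lv, "quartile": q,
                                 "mfi": 20.0, "n_voxels": 10})
        return pd.DataFrame(rows)

    def _participants(self, n):
        return pd.DataFrame({
            "participant_id": [f"S{i:03d}" for i in range(n)],
            "age": 30.0, "sex": "female", "bmi": 24.0,
            "ndi_percent": 5.0, "group": "recovered",
        })

    def test_complete_table_row_count(self):
        parts = self._participants(61)
        table = build_analysis_table(self._records(parts), parts)
        assert len(table) == expected_row_count(61) == 976

    def test_missing_cell_drops_one_row(self):
        parts = self._participants(61)
        recs = self._records(parts).iloc[1:]
        table = build_analysis_table(recs, parts)
        assert len(table) == 975

    def test_round_trip_csv(self, tmp_path):
        parts = self._participants(3)
        table = build_analysis_table(self._records(parts), parts)
        path = tmp_path / "analysis.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)

    def test_unknown_participant_is_join_error(self):
        parts = self._participants(2)
        recs = self._records(self._participants(3))
        with pytest.raises(JoinError):
            build_analysis_table(recs, parts)
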