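"""The synthetic Dixon-cohort generator and its ground truth."""

import numpy as np
import pytest

from mfiq.fatwater import compute_mfi_map
from mfiq.pipeline import analyze_dataset
from mfiq.synthetic import (
    ConfigurationError,
    GenerationError,
    MaskMorphology,
    default_profiles,
    generate_fatwater,
    generate_metadata,
    generate_mask,
    noise_free,
    null_profiles,
    participants_to_frame,
)


class TestMetadata:
    def test_study_group_sizes(self):
        ps = generate_metadata(10, 26, 25, seed=1)
        assert len(ps) == 61
        sizes = {g: sum(p.group == g for p in ps) for g in ("severe", "mild", "recovered")}
        assert sizes == {"severe": 10, "mild": 26, "recovered": 25}

    def test_single_recovered_participant_ndi_band(self):
        (p,) = generate_metadata(0, 0, 1, seed=7)
        assert p.group == "recovered"
        assert 0 <= p.ndi_percent < 10

    def test_ndi_within_band_and_demographics_within_invariants(self):
        for p in generate_metadata(10, 26, 25, seed=2):
            lo, hi = {"severe": (30, 60), "mild": (10, 30), "recovered": (0, 10)}[p.group]
            assert lo <= p.ndi_percent < hi
            assert 18 <= p.age <= 65
            assert p.bmi > 0

    def test_deterministic_given_seed(self):
        a = generate_metadata(3, 3, 3, seed=9)
        b = generate_metadata(3, 3, 3, seed=9)
        assert a == b
        c = generate_metadata(3, 3, 3, seed=10)
        assert a != c

    def test_overlapping_ndi_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_metadata(1, 1, 1, ndi_bands={"severe": (25, 60), "mild": (10, 30),
                                                  "recovered": (0, 10)}, seed=0)

    def test_band_inconsistent_with_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_metadata(1, 1, 1, ndi_bands={"severe": (20, 60), "mild": (10, 20),
                                                  "recovered": (0, 10)}, seed=0)


class TestMask:
    def test_right_side_convention(self):
        m = generate_mask((64, 128), "right", MaskMorphology(20, 8), landmark_column=64)
        cols = np.nonzero(m)[1]
        assert cols.min() > 64

    def test_mirror_symmetry(self):
        right = generate_mask((64, 129), "right", MaskMorphology(20, 8), landmark_column=64)
        left = generate_mask((64, 129), "left", MaskMorphology(20, 8), landmark_column=64)
        assert np.nonzero(left)[1].max() < 64
        assert left.sum() == right.sum()
        np.testing.assert_array_equal(left, right[:, ::-1])

    def test_degenerate_semi_axes(self):
        m = generate_mask((20, 40), "right", MaskMorphology(1, 1), landmark_column=10)
        assert m.sum() >= 1

    def test_ellipse_must_fit(self):
        with pytest.raises(GenerationError):
            generate_mask((20, 40), "right", MaskMorphology(30, 5), landmark_column=10)


class TestFatWaterGeneration:
    def test_zero_noise_inversion_through_pipeline(self, noisefree_dataset):
        """With all SDs zero the pipeline recovers the profile means exactly."""
        out = analyze_dataset(noisefree_dataset)
        merged = out.analysis_table.merge(
            noisefree_dataset.ground_truth.cells,
            on=["participant_id", "level", "quartile"],
        )
        assert len(merged) == len(out.analysis_table)
        np.testing.assert_allclose(merged["mfi"], merged["true_mfi"], atol=1e-9)

    def test_noisy_quartile_mean_within_monte_carlo_error(self):
        """One participant, >= 1e4 voxels per quartile: the pipeline-recovered
        quartile mean agrees with an independent scalar Monte-Carlo simulation
        of the stated noise model within 3 combined standard errors."""
        ps = generate_metadata(0, 0, 1, seed=5)
        noise_sd, w_ref = 50.0, 1000.0
        profiles = default_profiles(participant_sd=0.0, slope_sd=0.0, voxel_noise_sd=noise_sd)
        ds = generate_fatwater(ps, profiles, seed=5, water_reference=w_ref,
                               grid_shape=(160, 320), morphology=MaskMorphology(70, 32),
                               landmark_column=160)
        img = ds.imaging[0]
        mfi = compute_mfi_map(img.volume)
        truth = ds.ground_truth.cells.set_index(["level", "quartile"])["true_mfi"]
        oracle_rng = np.random.default_rng(987)
        n_oracle = 200_000
        for level, (lo, hi) in img.volume.levels.items():
            for q in (1, 2, 3, 4):
                sel = (img.labels[lo:hi + 1] == q) & mfi.valid[lo:hi + 1]
                vals = mfi.values[lo:hi + 1][sel]
                assert vals.size >= 10_000
                # independent oracle: simulate the stated voxel model directly
                m = truth[level, q] / 100.0
                f = np.clip(w_ref * m + oracle_rng.normal(0, noise_sd, n_oracle), 0, None)
                w = np.clip(w_ref * (1 - m) + oracle_rng.normal(0, noise_sd, n_oracle), 0, None)
                ref = 100.0 * f / (f + w)
                se = np.sqrt(vals.var(ddof=1) / vals.size + ref.var(ddof=1) / n_oracle)
                assert abs(vals.mean() - ref.mean()) < 3 * se

    def test_identical_seed_gives_bit_identical_volumes(self, tiny_cohort):
        prof = default_profiles()
        a = generate_fatwater(tiny_cohort, prof, seed=11)
        b = generate_fatwater(tiny_cohort, prof, seed=11)
        for ia, ib in zip(a.imaging, b.imaging):
            np.testing.assert_array_equal(ia.volume.fat, ib.volume.fat)
            np.testing.assert_array_equal(ia.volume.water, ib.volume.water)

    def test_water_reference_must_be_positive(self, tiny_cohort):
        with pytest.raises(ConfigurationError):
            generate_fatwater(tiny_cohort, default_profiles(), water_reference=0.0, seed=1)


class TestDefaultProfileGeography:
    """The calibrated defaults encode the qualitative MFI geography."""

    def test_q1_highest_within_every_group_and_level(self):
        for (group, level), prof in default_profiles().items():
            q1, q2, q3, q4 = prof.means
            assert q1 > max(q2, q3, q4)
            assert q2 >= q3
            assert abs(q3 - q4) < 1e-9

    def test_symptomatic_elevation_medial_only(self):
        prof = default_profiles()
        for level in ("C4", "C5", "C6", "C7"):
            rec = prof[("recovered", level)].means
            for g in ("severe", "mild"):
                sym = prof[(g, level)].means
                assert sym[0] > rec[0]  # Q1 elevated at every level
                assert sym[2] == rec[2] and sym[3] == rec[3]  # never lateral
                if level in ("C4", "C5"):
                    assert sym[1] > rec[1]  # Q2 elevated at C4-C5 only
                else:
                    assert sym[1] == rec[1]

    def test_ground_truth_reflects_profile_ordering(self, tiny_cohort):
        ds = generate_fatwater(tiny_cohort, noise_free(default_profiles()), seed=3)
        cells = ds.ground_truth.cells.merge(
            participants_to_frame(tiny_cohort), on="participant_id"
        )
        means = cells.groupby(["group", "level", "quartile"])["true_mfi"].mean()
        for g in ("severe", "mild", "recovered"):
            for lv in ("C4", "C5", "C6", "C7"):
                assert means[g, lv, 1] == max(means[g, lv, q] for q in (1, 2, 3, 4))

    def test_null_profiles_have_no_group_differences(self):
        prof = null_profiles()
        for level in ("C4", "C5", "C6", "C7"):
            assert prof[("severe", level)].means == prof[("recovered", level)].means
            assert prof[("mild", level)].means == prof[("recovered", level)].means
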