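"""Synthetic Dixon-cohort generator with known ground truth.

Emulates the analysed study conditions: a whiplash cohort imaged at 12 months
post collision (severe n=10 / mild n=26 / recovered n=25), axial fat/water
slice stacks covering C4-C7 with bilateral elliptical deep-extensor ROIs, a
medial->lateral MFI gradient (Q1 highest), group-specific elevation of the
medial quartiles in the symptomatic groups (Q1 at every level, Q2 at C4-C5
only), participant-level random intercepts and medial-lateral slopes, and
additive Gaussian voxel noise on the fat and water intensities.

The per-voxel target fat fraction for a voxel in quartile q is

    m = clip(profile_mean[group, level, q] + b0 + b1 * q, 0, 100)

with participant random effects b0 ~ N(0, participant_sd^2) and
b1 ~ N(0, slope_sd^2). Intensities are synthesised by inverting the MFI
ratio: water = W * (1 - m/100) + e_W, fat = W * m/100 + e_F, with e ~
N(0, voxel_noise_sd^2) and intensities truncated at 0. With all noise and
random-effect scales at zero the full pipeline reproduces the profile means
exactly.

Per-quartile profile means are generator calibration, not published values
(the source study reports its quartile profile only graphically); they are
chosen so the qualitative geography above emerges at the study's group sizes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from mfiq.cohort import GROUPS, assign_group
from mfiq.fatwater import LEVELS, FatWaterVolume
from mfiq.quartiles import SIDE_CODES, SIDES, MuscleMask, medial_lateral_coordinate, partition_quartiles


class ConfigurationError(ValueError):
    """Generator configuration is internally inconsistent."""


class GenerationError(RuntimeError):
    """A synthetic artefact could not be produced (e.g. empty rasterized ROI)."""


@dataclass(frozen=True)
class Participant:
    """One cohort member: demographics plus 12-month disability and group."""

    id: str
    age: float  # years
    sex: str  # "female" | "male"
    bmi: float  # kg/m^2
    ndi_percent: float  # 0-100
    group: str  # severe | mild | recovered (pure function of ndi_percent)


@dataclass(frozen=True)
class GroupDemographics:
    """Per-group demographic sampling parameters (age years, BMI kg/m^2)."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    female_fraction: float


#: Demographics matching the analysed sub-study's group descriptives.
DEFAULT_DEMOGRAPHICS: dict[str, GroupDemographics] = {
    "severe": GroupDemographics(37.0, 12.5, 25.7, 2.8, 0.80),
    "mild": GroupDemographics(37.9, 12.5, 23.8, 3.7, 23 / 26),
    "recovered": GroupDemographics(31.5, 10.7, 23.6, 3.1, 14 / 25),
}

#: NDI sampling bands per group; uniform within band, consistent with the
#: classification thresholds (severe >= 30, mild [10, 30), recovered < 10).
DEFAULT_NDI_BANDS: dict[str, tuple[float, float]] = {
    "severe": (30.0, 60.0),
    "mild": (10.0, 30.0),
    "recovered": (0.0, 10.0),
}

AGE_RANGE = (18.0, 65.0)  # study inclusion band


def _subseed(seed: int, *parts: int | str) -> np.random.Generator:
    """Independent generator derived from a master seed and a structured key.

    Each participant/replicate stream depends only on the master seed and its
    key, never on generation order.
    """
    h = hashlib.sha256(("|".join([str(seed), *map(str, parts)])).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Resampling-based truncated normal draw (bounds far from the bulk)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_metadata(
    n_severe: int,
    n_mild: int,
    n_recovered: int,
    demographics: Mapping[str, GroupDemographics] | None = None,
    ndi_bands: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[Participant]:
    """Sample participant metadata with exact per-group counts.

    NDI is drawn uniformly within each group's band (the least-assumptive
    band-respecting choice); ages are truncated to the study inclusion band
    [18, 65]; BMI is truncated below at 15 kg/m^2. Deterministic given seed.
    """
    demographics = dict(demographics or DEFAULT_DEMOGRAPHICS)
    ndi_bands = dict(ndi_bands or DEFAULT_NDI_BANDS)
    counts = {"severe": n_severe, "mild": n_mild, "recovered": n_recovered}
    if any(c < 0 for c in counts.values()):
        raise ConfigurationError("group counts must be >= 0")

    bands = sorted(ndi_bands.items(), key=lambda kv: kv[1][0])
    for (g1, (_, h1)), (g2, (l2, _)) in zip(bands, bands[1:]):
        if l2 < h1:
            raise ConfigurationError(f"NDI bands for {g1} and {g2} overlap")
    for group, (lo, hi) in ndi_bands.items():
        probe = (lo + min(hi, lo + 1e-6)) / 2  # interior point of [lo, hi)
        if assign_group(lo) != group or assign_group(probe) != group:
            raise ConfigurationError(
                f"NDI band [{lo}, {hi}) for {group!r} is inconsistent with the group thresholds"
            )

    participants: list[Participant] = []
    idx = 0
    for group in GROUPS:
        demo = demographics[group]
        lo, hi = ndi_bands[group]
        for _ in range(counts[group]):
            rng = _subseed(seed, "meta", idx)
            ndi = float(rng.uniform(lo, hi))
            age = _truncated_normal(rng, demo.age_mean, demo.age_sd, *AGE_RANGE)
            bmi = _truncated_normal(rng, demo.bmi_mean, demo.bmi_sd, 15.0, 60.0)
            sex = "female" if rng.uniform() < demo.female_fraction else "male"
            assert assign_group(ndi) == group
            participants.append(
                Participant(id=f"S{idx:03d}", age=age, sex=sex, bmi=bmi,
                            ndi_percent=ndi, group=group)
            )
            idx += 1
    return participants


def participants_to_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    """Tidy metadata table (one row per participant)."""
    return pd.DataFrame(
        [
            {
                "participant_id": p.id,
                "age": p.age,
                "sex": p.sex,
                "bmi": p.bmi,
                "ndi_percent": p.ndi_percent,
                "group": p.group,
            }
            for p in participants
        ]
    )


# ---------------------------------------------------------------------------
# Quartile MFI profiles


@dataclass(frozen=True)
class QuartileProfile:
    """Ground-truth MFI profile for one group at one vertebral level.

    ``means`` are the Q1..Q4 population MFI means in percent; ``participant_sd``
    and ``slope_sd`` scale the per-participant random intercept and
    medial-lateral slope (percent per quartile step); ``voxel_noise_sd`` is the
    intensity-unit SD of the additive fat/water noise.
    """

    group: str
    level: str
    means: tuple[float, float, float, float]
    participant_sd: float = 3.0
    slope_sd: float = 0.8
    voxel_noise_sd: float = 30.0

    def __post_init__(self) -> None:
        if len(self.means) != 4 or not all(0 <= m <= 100 for m in self.means):
            raise ConfigurationError("profile means must be four values in [0, 100]")
        if min(self.participant_sd, self.slope_sd, self.voxel_noise_sd) < 0:
            raise ConfigurationError("profile SDs must be >= 0")


ProfileSet = dict[tuple[str, str], QuartileProfile]

# Calibrated defaults: Q1 > Q2 >= Q3 ~ Q4 within every group; symptomatic
# groups elevated in Q1 at every level and in Q2 at C4-C5 only.
_RECOVERED_MEANS = (20.0, 14.0, 12.0, 12.0)
_Q2_ELEVATED_LEVELS = ("C4", "C5")


def default_profiles(
    participant_sd: float = 3.0, slope_sd: float = 0.8, voxel_noise_sd: float = 30.0
) -> ProfileSet:
    """Default ground-truth profiles reproducing the qualitative MFI geography."""
    profiles: ProfileSet = {}
    for level in LEVELS:
        q2_bump_mild = 3.0 if level in _Q2_ELEVATED_LEVELS else 0.0
        q2_bump_severe = 4.0 if level in _Q2_ELEVATED_LEVELS else 0.0
        means = {
            "recovered": _RECOVERED_MEANS,
            "mild": (26.0, 14.0 + q2_bump_mild, 12.0, 12.0),
            "severe": (28.0, 14.0 + q2_bump_severe, 12.0, 12.0),
        }
        for group in GROUPS:
            profiles[(group, level)] = QuartileProfile(
                group=group,
                level=level,
                means=means[group],
                participant_sd=participant_sd,
                slope_sd=slope_sd,
                voxel_noise_sd=voxel_noise_sd,
            )
    return profiles


def null_profiles(**kwargs) -> ProfileSet:
    """Profiles with no group differences (every group gets the recovered profile)."""
    base = default_profiles(**kwargs)
    return {
        (group, level): replace(base[("recovered", level)], group=group)
        for group in GROUPS
        for level in LEVELS
    }


def noise_free(profiles: ProfileSet) -> ProfileSet:
    """Copy of a profile set with every stochastic scale set to zero."""
    return {
        key: replace(p, participant_sd=0.0, slope_sd=0.0, voxel_noise_sd=0.0)
        for key, p in profiles.items()
    }


# ---------------------------------------------------------------------------
# Mask and volume synthesis


@dataclass(frozen=True)
class MaskMorphology:
    """Elliptical ROI shape: semi-axes (lateral, vertical) in voxels plus the
    offset of the medial ROI edge from the landmark column."""

    semi_lateral: int = 20
    semi_vertical: int = 8
    medial_offset: int = 1
    center_row: int | None = None  # defaults to the grid's middle row


def generate_mask(
    grid_shape: tuple[int, int],
    side: str,
    morphology: MaskMorphology = MaskMorphology(),
    landmark_column: int = 64,
) -> np.ndarray:
    """Rasterize one side's elliptical ROI on a single slice.

    The ROI's medial-most column sits ``medial_offset`` columns lateral of the
    landmark on the requested side; mirrored left/right calls produce
    mirror-image masks with identical voxel counts.
    """
    n_rows, n_cols = grid_shape
    if not 0 <= landmark_column < n_cols:
        raise GenerationError("landmark column outside grid")
    r0 = morphology.center_row if morphology.center_row is not None else n_rows // 2
    a, b = morphology.semi_lateral, morphology.semi_vertical
    if side == "right":
        c0 = landmark_column + morphology.medial_offset + a
    elif side == "left":
        c0 = landmark_column - morphology.medial_offset - a
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not (0 <= c0 - a and c0 + a < n_cols and 0 <= r0 - b and r0 + b < n_rows):
        raise GenerationError("ellipse does not fit inside the grid")
    rr, cc = _draw_ellipse(r0, c0, b + 0.5, a + 0.5, shape=grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise GenerationError("rasterized ROI is empty")
    return mask


@dataclass
class GroundTruth:
    """True per-cell MFI means and realized random effects for one cohort."""

    cells: pd.DataFrame  # participant_id, level, quartile, true_mfi
    random_effects: pd.DataFrame  # participant_id, intercept, slope


@dataclass
class SyntheticParticipantImaging:
    """Generated imaging for one participant: volumes, mask, quartile labels."""

    participant: Participant
    volume: FatWaterVolume
    mask: MuscleMask
    labels: np.ndarray = field(repr=False)


@dataclass
class SyntheticDataset:
    """A complete generated cohort with its ground truth."""

    participants: list[Participant]
    imaging: list[SyntheticParticipantImaging]
    ground_truth: GroundTruth
    seed: int


def generate_fatwater(
    participants: Sequence[Participant],
    profiles: ProfileSet,
    slices_per_level: int = 3,
    water_reference: float = 1000.0,
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 128),
    morphology: MaskMorphology = MaskMorphology(),
    landmark_column: int = 64,
    levels: Sequence[str] = LEVELS,
) -> SyntheticDataset:
    """Synthesize fat/water volumes, masks and ground truth for a cohort.

    Each participant receives ``len(levels) * slices_per_level`` axial slices
    with bilateral elliptical ROIs; every ROI voxel's intensities invert the
    MFI ratio at that voxel's target fraction (group profile + participant
    random effects), plus truncated Gaussian voxel noise. Bit-identical for a
    fixed seed; each participant's stream depends only on (seed, participant).
    """
    if water_reference <= 0:
        raise ConfigurationError("water_reference must be > 0")
    if slices_per_level < 3:
        raise ConfigurationError("slices_per_level must be >= 3")

    n_slices = len(levels) * slices_per_level
    level_ranges = {
        level: (i * slices_per_level, (i + 1) * slices_per_level - 1)
        for i, level in enumerate(levels)
    }

    # One mask geometry shared by the cohort (anatomy is not the object of study).
    slice_rois = np.zeros((n_slices,) + tuple(grid_shape), dtype=np.int8)
    for side in SIDES:
        m = generate_mask(grid_shape, side, morphology, landmark_column)
        slice_rois[:, m] = SIDE_CODES[side]
    mask = MuscleMask(rois=slice_rois, landmark_columns=np.full(n_slices, landmark_column))

    # Quartile labels are identical on every slice for this geometry.
    label_slice = np.zeros(grid_shape, dtype=np.int8)
    for side in SIDES:
        roi = mask.side_roi(0, side)
        coords = medial_lateral_coordinate(roi, landmark_column, side)
        label_slice = np.where(roi, partition_quartiles(roi, coords), label_slice)
    labels = np.broadcast_to(label_slice, (n_slices,) + tuple(grid_shape)).copy()

    imaging: list[SyntheticParticipantImaging] = []
    truth_rows: list[dict] = []
    re_rows: list[dict] = []
    for p in participants:
        rng = _subseed(seed, "imaging", p.id)
        any_profile = profiles[(p.group, levels[0])]
        b0 = rng.normal(0.0, any_profile.participant_sd) if any_profile.participant_sd else 0.0
        b1 = rng.normal(0.0, any_profile.slope_sd) if any_profile.slope_sd else 0.0
        re_rows.append({"participant_id": p.id, "intercept": b0, "slope": b1})

        fat = np.zeros((n_slices,) + tuple(grid_shape), dtype=float)
        water = np.zeros_like(fat)
        for level, (lo, hi) in level_ranges.items():
            prof = profiles[(p.group, level)]
            target = np.zeros(4)
            for q in range(1, 5):
                m = float(np.clip(prof.means[q - 1] + b0 + b1 * q, 0.0, 100.0))
                target[q - 1] = m
                truth_rows.append(
                    {"participant_id": p.id, "level": level, "quartile": q, "true_mfi": m}
                )
            for s in range(lo, hi + 1):
                in_roi = labels[s] > 0
                m_map = np.zeros(grid_shape, dtype=float)
                m_map[in_roi] = target[labels[s][in_roi] - 1]
                f = water_reference * m_map / 100.0
                w = water_reference * (1.0 - m_map / 100.0)
                if prof.voxel_noise_sd > 0:
                    f = f + rng.normal(0.0, prof.voxel_noise_sd, grid_shape)
                    w = w + rng.normal(0.0, prof.voxel_noise_sd, grid_shape)
                    f = np.clip(f, 0.0, None)
                    w = np.clip(w, 0.0, None)
                fat[s][in_roi] = f[in_roi]
                water[s][in_roi] = w[in_roi]
        volume = FatWaterVolume(fat=fat, water=water, levels=dict(level_ranges))
        imaging.append(
            SyntheticParticipantImaging(participant=p, volume=volume, mask=mask, labels=labels)
        )

    truth = GroundTruth(
        cells=pd.DataFrame(truth_rows),
        random_effects=pd.DataFrame(re_rows, columns=["participant_id", "intercept", "slope"]),
    )
    return SyntheticDataset(
        participants=list(participants), imaging=imaging, ground_truth=truth, seed=seed
    )


# ---------------------------------------------------------------------------
# Table-level simulation (fast path for operating-characteristic studies)


def simulate_analysis_table(
    participants: Sequence[Participant],
    profiles: ProfileSet,
    measurement_sd: float = 1.0,
    seed: int = 0,
    levels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Simulate the analysis table directly at the record level.

    The voxel stage of the pipeline is a linear average, so a record is
    distributed as the cell's true mean plus a residual; ``measurement_sd``
    (percent MFI) stands for the pooled voxel noise and the slice/segmentation
    variability a real measurement carries. Used for power and type-I-error
    studies where re-rasterising volumes per replicate adds nothing.
    """
    rows: list[dict] = []
    for p in participants:
        rng = _subseed(seed, "table", p.id)
        any_profile = profiles[(p.group, levels[0])]
        b0 = rng.normal(0.0, any_profile.participant_sd) if any_profile.participant_sd else 0.0
        b1 = rng.normal(0.0, any_profile.slope_sd) if any_profile.slope_sd else 0.0
        for level in levels:
            prof = profiles[(p.group, level)]
            for q in range(1, 5):
                mu = prof.means[q - 1] + b0 + b1 * q
                eps = rng.normal(0.0, measurement_sd) if measurement_sd else 0.0
                rows.append(
                    {
                        "participant_id": p.id,
                        "level": level,
                        "quartile": q,
                        "mfi": float(np.clip(mu + eps, 0.0, 100.0)),
                        "n_voxels": 1,
                        "age": p.age,
                        "sex": p.sex,
                        "bmi": p.bmi,
                        "ndi_percent": p.ndi_percent,
                        "group": p.group,
                    }
                )
    return pd.DataFrame(rows)
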