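import numpy as np
import pytest

from mfiq.synthetic import (
    default_profiles,
    generate_fatwater,
    generate_metadata,
    noise_free,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six participants (2/2/2), deterministic."""
    return generate_metadata(2, 2, 2, seed=3)


@pytest.fixture(scope="session")
def noisefree_dataset(tiny_cohort):
    """Noise-free synthetic imaging for the tiny cohort (all SDs zero)."""
    return generate_fatwater(tiny_cohort, noise_free(default_profiles()), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape=(40, 60), n_seeds=6, max_voxels=500, side="right", landmark=5):
    """Random connected-ish blob ROI strictly lateral of the landmark column."""
    mask = np.zeros(shape, dtype=bool)
    rows = rng.integers(2, shape[0] - 2, n_seeds)
    cols = rng.integers(landmark + 1, shape[1] - 2, n_seeds)
    for r, c in zip(rows, cols):
        rr = rng.integers(1, 6)
        mask[max(0, r - rr):r + rr, max(landmark + 1, c - rr):c + rr] = True
    if mask.sum() > max_voxels:
        on = np.argwhere(mask)
        keep = on[rng.permutation(len(on))[:max_voxels]]
        mask = np.zeros(shape, dtype=bool)
        mask[keep[:, 0], keep[:, 1]] = True
    if side == "left":
        mask = mask[:, ::-1].copy()
    return mask
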