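import numpy as np
import pytest

from gbmgrade import MaskVolume, cohort_from_outcome_counts, cohort_from_prevalence_counts


def mask_from_indices(indices, shape, spacing=(1.0, 1.0, 1.0), origin=None):
    """Small helper: binary mask with foreground at the given index triples."""
    arr = np.zeros(shape, dtype=bool)
    for idx in indices:
        arr[tuple(idx)] = True
    return MaskVolume.from_array(arr, spacing=spacing, origin=origin)


def random_blob(rng, n_voxels, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0)):
    """Mask with n_voxels random distinct foreground voxels."""
    flat = rng.choice(np.prod(shape), size=n_voxels, replace=False)
    arr = np.zeros(np.prod(shape), dtype=bool)
    arr[flat] = True
    return MaskVolume.from_array(arr.reshape(shape), spacing=spacing)


@pytest.fixture(scope="session")
def outcome_cohort():
    """The 88-patient grade-by-outcome reconstruction (14/45/29 classes)."""
    return cohort_from_outcome_counts()


@pytest.fixture(scope="session")
def prevalence_cohort():
    """The 88-patient feature-prevalence reconstruction (68/29/38/62/61)."""
    return cohort_from_prevalence_counts()
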