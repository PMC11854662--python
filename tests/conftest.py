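import dataclasses

import numpy as np
import pytest

from petww.phantom import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


#: Compact phantom used throughout the suite: 40^3 grid at 3 mm, 3 lesions.
SMALL_PHANTOM = PhantomSpec(
    grid_shape=(40, 40, 40),
    voxel_spacing=(3.0, 3.0, 3.0),
    n_lesions=3,
    lesion_radius_range=(7.0, 12.0),
    liver_center=(13, 13, 13),
)


def small_phantom(seed: int, **overrides) -> PhantomSpec:
    return dataclasses.replace(SMALL_PHANTOM, seed=seed, **overrides)


def small_cohort_spec(seed: int, **overrides) -> CohortSpec:
    defaults = dict(
        n_subjects=20,
        lesion_count_jitter=1,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def phantom_pair():
    """One small phantom volume with its ground truth."""
    return generate_phantom(small_phantom(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort on the compact grid, no batch effects."""
    return generate_cohort(small_cohort_spec(seed=7), SMALL_PHANTOM)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
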