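"""Shared fixtures: random tumor maps and small phantom bundles."""

import logging

import numpy as np
import pytest

from gliorad import LabelVolume, RegionMask

logging.getLogger("gliorad").setLevel(logging.ERROR)


def random_tumor_map(rng: np.random.Generator, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Random valid tumor map: labels in {0, 1, 2, 4} with a nonempty WT."""
    while True:
        data = rng.choice([0, 0, 0, 1, 2, 4], size=shape).astype(np.int16)
        if (data > 0).any():
            return LabelVolume(data, spacing)


def random_blob(rng: np.random.Generator, shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0)) -> RegionMask:
    """Random connected-ish blob: a ball at a random center with radius jitter."""
    center = rng.uniform(6, np.asarray(shape) - 6)
    radius = rng.uniform(2.5, 6.0)
    idx = np.indices(shape, dtype=float)
    dist = np.sqrt(sum((idx[a] - center[a]) ** 2 for a in range(3)))
    noise = rng.normal(0, 0.6, size=shape)
    return RegionMask(dist + noise <= radius, spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_bundle():
    """One 48-cube subject with two scheme predictions (session-cached)."""
    from gliorad import CohortRole, generate_cohort
    from gliorad.synthetic_cohort import DEFAULT_SCHEME_PROFILES, PhantomSpec

    return generate_cohort(
        3,
        CohortRole.TESTING_A,
        master_seed=77,
        scheme_profiles=DEFAULT_SCHEME_PROFILES[:2],
        spec=PhantomSpec(grid_shape=(48, 48, 48)),
    )
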