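import dataclasses

import numpy as np
import pytest

from rsnet.synthetic import CohortSpec, EffectSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """Four-per-group, 40-node, 300-volume cohort for fast end-to-end tests."""
    return CohortSpec(
        n_lesion=4,
        n_sham=4,
        n_nodes=40,
        n_hemisphere=20,
        n_volumes=300,
        n_modules=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_null_cohort(small_cohort_spec):
    return generate_cohort(small_cohort_spec, EffectSpec(null_flag=True))


@pytest.fixture(scope="session")
def small_effect_cohort(small_cohort_spec):
    effect = EffectSpec(
        reduced_block=frozenset(range(6)),
        increased_block=frozenset({12, 13, 32, 33}),
        reduction_factor=0.5,
        increase_factor=1.3,
    )
    return generate_cohort(small_cohort_spec, effect)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort_spec(small_cohort_spec) -> CohortSpec:
    """Two-per-group variant for error-path and determinism checks."""
    return dataclasses.replace(small_cohort_spec, n_lesion=2, n_sham=2)
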