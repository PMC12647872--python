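import numpy as np
import pytest

from pdprog import (
    GeneratorConfig,
    default_profiles,
    fit_normalization,
    generate,
    impute,
    normalize,
)


@pytest.fixture(scope="session")
def small_cohort_with_labels():
    """Small noisy cohort with missingness: 6 participants per subtype."""
    cfg = GeneratorConfig(
        n_per_subtype={"rapid": 6, "moderate": 6, "slow": 6, "HC": 6},
        seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_with_labels):
    return small_cohort_with_labels[0]


@pytest.fixture(scope="session")
def small_imputed(small_cohort):
    return impute(small_cohort)


@pytest.fixture(scope="session")
def small_normalized(small_imputed):
    return normalize(small_imputed, fit_normalization(small_imputed))


@pytest.fixture(scope="session")
def clean_cohort_with_labels():
    """Zero-noise, fully observed cohort: the separable regime."""
    cfg = GeneratorConfig(
        n_per_subtype={"rapid": 5, "moderate": 5, "slow": 5, "HC": 5},
        missing_rate_even=0.0,
        missing_rate_odd=0.0,
        profiles=default_profiles(noise_sd=0.0),
        seed=3,
    )
    return generate(cfg)
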