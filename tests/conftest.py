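import numpy as np
import pytest

from cohsel import (CohortSpec, build_feature_matrix, generate_cohort)

#: the five pair-band features carrying the planted class effect
#: (MSC 0.6 vs 0.2) in the default cohort spec
PLANTED_FEATURES = frozenset({
    "F3-C3_alpha", "P4-T6_alpha", "C3-C4_theta", "P3-T5_theta", "F3-F4_delta",
})


@pytest.fixture(scope="session")
def planted_features():
    """Feature matrix of the default planted cohort: 46 + 55 subjects,
    180 s at 250 Hz, five informative pair-band features."""
    spec = CohortSpec(seed=7)
    return build_feature_matrix(generate_cohort(spec))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast cohort (8 + 8 subjects, 20 s) for pipeline tests."""
    spec = CohortSpec(n_per_class=(8, 8), duration_s=20.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return build_feature_matrix(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
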