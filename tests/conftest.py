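import numpy as np
import pytest

from headachedx import CohortSpec, fixture_knowledge_base, generate_cohort


@pytest.fixture(scope="session")
def kb():
    return fixture_knowledge_base()


@pytest.fixture(scope="session")
def noise_free_cohort(kb):
    """n = 300 migbase-mix cohort with no feature noise (perfectly separable)."""
    return generate_cohort(kb, CohortSpec(n=300, noise_rate=0.0, seed=42))


@pytest.fixture(scope="session")
def noisy_cohort(kb):
    """n = 849 cohort at the default 5% feature-noise rate."""
    return generate_cohort(kb, CohortSpec(n=849, noise_rate=0.05, seed=42))


def random_feature_vector(vocab, rng: np.random.Generator, label=None):
    """A uniformly random *valid* feature vector over a vocabulary."""
    from headachedx import FeatureVector

    values = {}
    for spec in vocab:
        if spec.is_set_valued:
            values[spec.name] = frozenset(
                v for v in spec.domain if rng.random() < 0.5
            )
        else:
            values[spec.name] = spec.domain[rng.integers(len(spec.domain))]
    return FeatureVector(values, label)
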