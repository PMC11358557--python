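import numpy as np
import pytest

import tseeg as T


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-structure dataset: 4 subjects x 3 trials/class, 30 s."""
    profiles = T.gamma_discriminative_profiles()
    return T.generate_dataset(
        profiles, n_subjects=4, trials_per_class=3, duration_s=30.0, seed=123
    )


@pytest.fixture(scope="session")
def small_banded(small_dataset):
    return [
        T.extract_bands(tr, target_rate=None, crop_seconds=None)
        for tr in small_dataset.trials
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_distribution(rng, n_bins):
    p = rng.random(n_bins) + 1e-12
    p /= p.sum()
    p[-1] += 1.0 - p.sum()  # force exact unit sum
    return T.ProbabilityDistribution(
        probabilities=p, bin_edges=np.arange(n_bins + 1, dtype=float)
    )
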