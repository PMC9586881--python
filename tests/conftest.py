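import numpy as np
import pytest

from prevalence.core import PrevalencePosterior, TestOutcomes


@pytest.fixture
def posterior_6_10():
    return PrevalencePosterior(TestOutcomes(6, 10, 0.05))


def brute_force_hpdi(posterior, mass, n_grid=4001):
    """Shortest-interval search over a dense grid of lower-endpoint cdf
    values; independent oracle for PrevalencePosterior.hpdi."""
    t = np.linspace(0.0, 1.0 - mass, n_grid)
    lo = np.asarray(posterior.quantile(t))
    hi = np.asarray(posterior.quantile(t + mass))
    i = int(np.argmin(hi - lo))
    return float(lo[i]), float(hi[i])


@pytest.fixture
def random_outcomes():
    """20 seeded random (k, n, alpha) triples for normalization checks."""
    rng = np.random.default_rng(20220805)
    triples = []
    for _ in range(20):
        n = int(rng.integers(1, 80))
        k = int(rng.integers(0, n + 1))
        alpha = float(rng.uniform(0.005, 0.3))
        triples.append(TestOutcomes(k, n, alpha))
    return triples
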