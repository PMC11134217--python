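import numpy as np
import pytest

from neoconn.core import WeightedNetwork


def net_from(weights, labels=None) -> WeightedNetwork:
    w = np.asarray(weights, dtype=float)
    if labels is None:
        labels = [f"n{i}" for i in range(w.shape[0])]
    return WeightedNetwork(labels=labels, weights=w)


def random_net(rng, n_lo=4, n_hi=9, p_edge=0.6) -> WeightedNetwork | None:
    """Random small weighted graph; None if it came out edgeless."""
    n = int(rng.integers(n_lo, n_hi))
    w = rng.random((n, n)) * (rng.random((n, n)) < p_edge)
    w = np.triu(w, 1)
    w = w + w.T
    if np.count_nonzero(w) == 0:
        return None
    return net_from(w)


@pytest.fixture
def rng():
    return np.random.default_rng(20240528)


@pytest.fixture(scope="session")
def small_cohort():
    """A small full cohort reused by IO/pipeline-adjacent tests."""
    from neoconn.synthetic import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(n_treated=5, n_placebo=5, n_regions=15, n_frames=60, seed=42)
    )
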