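import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from docsvm import ScoredPredictions

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_force_auc(scores, labels) -> float:
    """Pairwise-count oracle: concordant pairs + half ties over all pos/neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_preds_factory(rng):
    """Factory of random probability-scale predictions with both classes present."""

    def make(n: int = 20, discretize: bool = False) -> ScoredPredictions:
        while True:
            labels = rng.integers(0, 2, size=n)
            if 0 < labels.sum() < n:
                break
        if discretize:
            scores = rng.choice(np.linspace(0, 1, 6), size=n)
        else:
            scores = rng.random(n)
        return ScoredPredictions(scores=scores, labels=labels)

    return make
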