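import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectrisk as sk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def jaccess():
    return sk.jaccess_model()


@pytest.fixture(scope="session")
def small_cohort(jaccess):
    """A modest synthetic cohort scored by the packaged model."""
    cfg = sk.CohortConfig(n=800, seed=7, label="unit")
    return sk.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_predictions(small_cohort, jaccess):
    return sk.score_cohort(small_cohort, jaccess)


@pytest.fixture
def prediction_factory():
    """Predictions with outcomes drawn from their own probabilities."""

    def make(n=500, seed=0, spread=1.0, shift=0.0, loc=-2.5):
        rng = np.random.default_rng(seed)
        logit = loc + spread * rng.normal(0, 1.2, n)
        from scipy.special import expit

        y = (rng.random(n) < expit(shift + logit)).astype(int)
        # guarantee both classes so concordance is defined
        if y.sum() == 0:
            y[np.argmax(logit)] = 1
        if y.sum() == n:
            y[np.argmin(logit)] = 0
        return sk.Predictions.from_logits(logit, y)

    return make
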