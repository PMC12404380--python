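import numpy as np
import pytest
from hypothesis import settings

from spamodel import CorrelationSet, SpamParams

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lon_sa() -> CorrelationSet:
    """Pooled loneliness / social-anxiety correlations (3-decimal)."""
    return CorrelationSet(0.603, 0.493, 0.379, 0.351, 0.552, 0.568, n=3995)


@pytest.fixture(scope="session")
def se_dep() -> CorrelationSet:
    """Pooled self-esteem / depression correlations (negative pair)."""
    return CorrelationSet(0.70, -0.51, -0.39, -0.41, -0.53, 0.53)


@pytest.fixture(scope="session")
def example_params() -> SpamParams:
    return SpamParams(a=0.79, s=+1, b=0.777, c=0.755, d=0.158)


def random_psd_correlation_set(rng: np.random.Generator) -> CorrelationSet:
    """Random strictly-PD 4x4 correlation matrix via a random factor model."""
    while True:
        loadings = rng.uniform(-0.9, 0.9, size=(4, 2))
        uniqueness = rng.uniform(0.2, 1.0, size=4)
        cov = loadings @ loadings.T + np.diag(uniqueness)
        scale = np.sqrt(np.diag(cov))
        corr = cov / np.outer(scale, scale)
        if np.linalg.eigvalsh(corr)[0] > 1e-6:
            return CorrelationSet.from_matrix(corr)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
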