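import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metstab import TraitMeans, datasets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def yield_means() -> TraitMeans:
    """Grain-yield cell means of the packaged 26x3 rice trial."""
    return datasets.load_trait_means("grain_yield")


@pytest.fixture(scope="session")
def dtm_means() -> TraitMeans:
    return datasets.load_trait_means("days_to_maturity")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220907)


def random_means(rng: np.random.Generator, g: int, e: int, scale: float = 1.0) -> TraitMeans:
    """Unstructured random cell-mean matrix for oracle comparisons."""
    matrix = 10.0 + scale * rng.standard_normal((g, e))
    return TraitMeans(
        "trait",
        [f"G{i}" for i in range(g)],
        [f"E{j}" for j in range(e)],
        matrix,
    )
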