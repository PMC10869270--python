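import numpy as np
import pytest

from stabmap import Dataset, MosaicScenario, generate_mosaic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_dataset(name, features, cells, values=None, rng=None):
    if values is None:
        rng = rng or np.random.default_rng(0)
        values = rng.normal(size=(len(features), len(cells)))
    return Dataset(name, list(features), list(cells), np.asarray(values, float))


@pytest.fixture
def small_mosaic():
    """Two overlapping-panel datasets from a shared 5-dim latent space."""
    scenario = MosaicScenario(
        n_features=120, latent_dim=5, n_types=3,
        cells_per_dataset=(200, 200),
        feature_panels=[list(range(90)), list(range(50, 120))],
        noise_sd=0.2, seed=11,
    )
    return generate_mosaic(scenario)


def brute_force_knn(train, query, k):
    """O(n^2) nearest-neighbor oracle; ties by training index."""
    out = []
    for q in query:
        d = np.linalg.norm(train - q, axis=1)
        order = np.lexsort((np.arange(len(train)), d))
        out.append(order[:k])
    return np.array(out)
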