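import numpy as np
import pytest

from rwrt.evaluate import loocv, single_network_baseline
from rwrt.synth import SyntheticConfig, degenerate_fixtures, generate
from rwrt.tensor import SimilarityTensor, build_tensor

FIXTURE_SEED = 1


def random_tensor(rng: np.random.Generator, n: int, m: int = 3, density: float = 0.4) -> SimilarityTensor:
    """Random symmetric nonnegative tensor with excluded diagonal."""
    layers = []
    for _ in range(m):
        upper = np.triu(rng.random((n, n)) < density, k=1) * rng.random((n, n))
        dense = upper + upper.T
        from scipy import sparse

        layers.append(sparse.csr_matrix(dense))
    return SimilarityTensor(n=n, layers=tuple(layers), layer_names=tuple(f"L{k}" for k in range(m)))


@pytest.fixture(scope="session")
def fixtures():
    return degenerate_fixtures()


@pytest.fixture(scope="session")
def planted_truth():
    """The standard planted-structure benchmark (200 proteins, 10 modules)."""
    return generate(SyntheticConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def planted_tensor(planted_truth):
    ds = planted_truth.dataset
    return build_tensor(ds.net, ds.domains, ds.catalog)


@pytest.fixture(scope="session")
def planted_loocv(planted_truth, planted_tensor):
    return loocv(planted_truth.dataset, tensor=planted_tensor)


@pytest.fixture(scope="session")
def planted_loocv_single(planted_truth, planted_tensor):
    baseline = single_network_baseline(planted_tensor)
    return loocv(planted_truth.dataset, tensor=baseline)


@pytest.fixture(scope="session")
def small_truth():
    """A smaller planted benchmark for walk-level tests."""
    return generate(
        SyntheticConfig(seed=7, n_proteins=60, n_modules=5, terms_per_module=2)
    )
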