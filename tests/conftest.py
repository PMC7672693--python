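import numpy as np
import pytest

from dynherit import GenotypeMatrix, PhenotypePanel, RelationshipMatrix, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotype():
    values = np.array(
        [
            [1, -1, 0, 1],
            [-1, 1, 0, -1],
            [0, 1, 1, -1],
            [1, 0, -1, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        values,
        [f"ind{i}" for i in range(4)],
        [f"m{j}" for j in range(4)],
    )


def random_psd(n: int, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
    a = rng.standard_normal((n, n))
    return a @ a.T / n + jitter * np.eye(n)


@pytest.fixture
def random_grm(rng):
    return RelationshipMatrix(random_psd(8, rng), [f"ind{i}" for i in range(8)])


@pytest.fixture
def small_panel(rng):
    grid = TimeGrid(np.array([0.0, 1.0, 2.5, 4.0]))
    values = rng.standard_normal((6, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
    return PhenotypePanel(values, grid, [f"ind{i}" for i in range(6)])
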