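import numpy as np
import pytest

from hcfmda import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    SyntheticSpec,
    make_dataset,
)


@pytest.fixture
def diamond_dag() -> DiseaseDAG:
    """A -> {B, C} -> D: two equal-length paths from the root to D."""
    return DiseaseDAG.from_edges([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture
def sibling_dag() -> DiseaseDAG:
    """Root A with two children B and C."""
    return DiseaseDAG.from_edges([("A", "B"), ("A", "C")])


@pytest.fixture
def small_assoc() -> AssociationMatrix:
    X = np.array(
        [
            [1, 0, 1, 0, 0],
            [0, 1, 0, 0, 1],
            [1, 1, 0, 1, 0],
            [0, 0, 1, 1, 0],
        ],
        dtype=float,
    )
    return AssociationMatrix(
        [f"d{i}" for i in range(4)], [f"m{j}" for j in range(5)], X
    )


def random_similarity(rng: np.random.Generator, n: int, labels=None) -> SimilarityMatrix:
    """Random symmetric similarity matrix, unit diagonal, total availability."""
    A = rng.random((n, n))
    S = (A + A.T) / 2.0
    np.fill_diagonal(S, 1.0)
    ids = labels if labels is not None else [f"e{i}" for i in range(n)]
    return SimilarityMatrix(list(ids), S, np.ones((n, n), dtype=bool))


@pytest.fixture
def tiny_dataset():
    """Small planted dataset shared by the slower integration tests."""
    return make_dataset(
        SyntheticSpec(n_diseases=12, n_mirnas=15, density=0.12, latent_rank=2, seed=7)
    )
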