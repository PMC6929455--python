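import numpy as np
import pytest

from rcmf import AssociationMatrix, DiseaseDAG, gip_kernel
from rcmf.synthetic import make_planted


@pytest.fixture
def chain_dag():
    """X -> P -> R (X is the most specific term)."""
    return DiseaseDAG(frozenset({"X", "P", "R"}),
                      frozenset({("X", "P"), ("P", "R")}))


@pytest.fixture
def diamond_dag():
    return DiseaseDAG(
        frozenset({"X", "P1", "P2", "R"}),
        frozenset({("X", "P1"), ("X", "P2"), ("P1", "R"), ("P2", "R")}),
    )


def random_association(rng: np.random.Generator, n: int, m: int,
                       density: float = 0.3) -> AssociationMatrix:
    values = (rng.random((n, m)) < density).astype(float)
    if values.sum() == 0:  # keep GIP well defined
        values[0, 0] = 1.0
    return AssociationMatrix(
        tuple(f"m{i}" for i in range(n)),
        tuple(f"d{j}" for j in range(m)),
        values,
    )


@pytest.fixture
def small_instance():
    """12x9 binary association matrix with GIP similarities."""
    Y = random_association(np.random.default_rng(0), 12, 9)
    return Y, gip_kernel(Y, "mirna"), gip_kernel(Y, "disease")


@pytest.fixture(scope="session")
def planted():
    """The 40x30 rank-2 benchmark instance used by end-to-end tests."""
    return make_planted(40, 30, 2, 0.15, 0.01, 0.1, seed=0)
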