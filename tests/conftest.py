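import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


from mirsea.core import AssociationTable, LabeledSimilarityMatrix, OntologyDAG


@pytest.fixture
def diamond_ontology() -> OntologyDAG:
    """7-node DAG: root r; a,b under r; c under a and b; d,e under c; f under d."""
    edges = [
        ("a", "r"), ("b", "r"),
        ("c", "a"), ("c", "b"),
        ("d", "c"), ("e", "c"),
        ("f", "d"),
    ]
    return OntologyDAG({"r", "a", "b", "c", "d", "e", "f"}, edges)


@pytest.fixture
def sibling_ontology() -> OntologyDAG:
    """Two sibling diseases under a single root."""
    return OntologyDAG({"root", "d1", "d2"}, [("d1", "root"), ("d2", "root")])


@pytest.fixture
def chain_ontology() -> OntologyDAG:
    """Chain d -> p -> root."""
    return OntologyDAG({"root", "p", "d"}, [("d", "p"), ("p", "root")])


def random_symmetric_matrix(n: int, seed: int) -> LabeledSimilarityMatrix:
    rng = np.random.default_rng(seed)
    upper = rng.uniform(0.0, 1.0, size=(n, n))
    values = np.triu(upper, 1)
    values = values + values.T
    np.fill_diagonal(values, 1.0)
    ids = [f"mir-{i:02d}" for i in range(n)]
    return LabeledSimilarityMatrix(ids, values)


@pytest.fixture
def random_matrix_factory():
    return random_symmetric_matrix
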