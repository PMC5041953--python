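import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from ilncsim import (
    DagGenParams,
    build_dag_from_edges,
    compute_ic,
    generate_dag,
    semantic_similarity_matrix,
)

#: Six-term worked fixture used throughout: R -> {A, B}, A -> {C, D}, B -> E.
TOY6_EDGES = [("R", "A"), ("R", "B"), ("A", "C"), ("A", "D"), ("B", "E")]


@pytest.fixture(scope="session")
def toy6():
    return build_dag_from_edges(TOY6_EDGES)


@pytest.fixture(scope="session")
def toy6_ic(toy6):
    return compute_ic(toy6)


@pytest.fixture(scope="session")
def toy6_ss(toy6, toy6_ic):
    return semantic_similarity_matrix(toy6, toy6_ic)


@pytest.fixture
def random_dag_factory():
    """Seeded random DAGs of a requested size, multi-parenting included."""

    def make(seed: int, n_terms: int = 30, multi_parent_prob: float = 0.15):
        return generate_dag(DagGenParams(n_terms=n_terms, max_depth=5,
                                         multi_parent_prob=multi_parent_prob,
                                         seed=seed))

    return make


def dag_edge_list(dag):
    """Raw (parent, child) edges of a DAG, for feeding the brute-force oracles."""
    return sorted(dag.graph.edges)
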