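"""Edge-based disease semantic similarity.

For a pair of disease terms *a*, *b* the similarity is assembled from three
non-negative components measured in information-content distance
``DIST_IC(x, y) = |IC(x) - IC(y)|``:

* ``alpha`` — specificity of the most informative common ancestor (MICA):
  its IC-distance from the root, which equals ``IC(MICA)`` since the root
  has IC 0.
* ``beta`` — generality of the query terms: the mean IC-distance from each
  term to its most informative leaf descendant (MIL). A leaf has beta 0.
* ``gamma`` — the summed IC-distance from each term up to the MICA.

These combine into

    SS(a, b) = alpha / (alpha + beta) * 1 / (1 + gamma)

so SS = 1 exactly for an identical leaf pair (beta = gamma = 0) and SS = 0
exactly when the terms meet only at the root (alpha = 0), including the
degenerate alpha = beta = 0 case. Natural log is assumed throughout: gamma
enters un-normalized through 1/(1+gamma), so the log base is part of the
model definition, not a free convention.

"Common ancestor" includes the query terms themselves, hence the MICA of an
ancestor/descendant pair is the ancestor and SS(leaf, leaf) = 1 falls out of
the formula rather than being special-cased.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dag_core import DiseaseDAG, ICTable, VIRTUAL_ROOT, ancestors, leaves_under
from .exceptions import UnknownTermError
from .matrix import SquareLabeledMatrix


@dataclass(frozen=True)
class SemSimComponents:
    """The MICA/MIL decomposition of one disease-pair similarity."""

    mica: str
    mil_a: str
    mil_b: str
    alpha: float
    beta: float
    gamma: float

    @property
    def similarity(self) -> float:
        if self.alpha == 0.0:
            return 0.0
        return (self.alpha / (self.alpha + self.beta)) * (1.0 / (1.0 + self.gamma))


class SemanticSimMatrix(SquareLabeledMatrix):
    """Symmetric disease-disease similarity matrix with entries in [0, 1]."""


def ic_distance(ic_table: ICTable, a: str, b: str) -> float:
    """Absolute information-content difference |IC(a) - IC(b)|."""
    return abs(ic_table[a] - ic_table[b])


def _most_informative(candidates, ic_table: ICTable) -> str:
    # Max IC; ties broken by lexicographically smallest id for reproducibility.
    return min(candidates, key=lambda t: (-ic_table[t], t))


def find_mica(dag: DiseaseDAG, ic_table: ICTable, a: str, b: str) -> str:
    """Most informative common ancestor of *a* and *b* (inclusive of both)."""
    common = ancestors(dag, a) & ancestors(dag, b)
    return _most_informative(common, ic_table)


def find_mil(dag: DiseaseDAG, ic_table: ICTable, a: str) -> str:
    """Most informative leaf descending from *a*; a leaf returns itself."""
    return _most_informative(leaves_under(dag, a), ic_table)


def semantic_components(dag: DiseaseDAG, ic_table: ICTable, a: str, b: str,
                        gamma_metric: str = "ic") -> SemSimComponents:
    """Compute the (MICA, MILs, alpha, beta, gamma) decomposition for a pair.

    ``gamma_metric="ic"`` (default) measures gamma in IC distance;
    ``"edges"`` counts shortest-path edges from the MICA instead — a
    sensitivity-analysis variant, not the model default.
    """
    mica = find_mica(dag, ic_table, a, b)
    mil_a = find_mil(dag, ic_table, a)
    mil_b = find_mil(dag, ic_table, b)
    alpha = ic_table[mica]
    beta = (ic_distance(ic_table, a, mil_a) + ic_distance(ic_table, b, mil_b)) / 2.0
    if gamma_metric == "ic":
        gamma = ic_distance(ic_table, mica, a) + ic_distance(ic_table, mica, b)
    elif gamma_metric == "edges":
        gamma = float(
            nx.shortest_path_length(dag.graph, mica, a)
            + nx.shortest_path_length(dag.graph, mica, b)
        )
    else:
        raise ValueError(f"unknown gamma metric {gamma_metric!r}")
    return SemSimComponents(mica=mica, mil_a=mil_a, mil_b=mil_b,
                            alpha=alpha, beta=beta, gamma=gamma)


def semantic_similarity(dag: DiseaseDAG, ic_table: ICTable, a: str, b: str,
                        gamma_metric: str = "ic") -> float:
    """SS(a, b) in [0, 1]; 0 when the pair meets only at the root."""
    return semantic_components(dag, ic_table, a, b, gamma_metric=gamma_metric).similarity


def semantic_similarity_matrix(dag: DiseaseDAG, ic_table: ICTable,
                               term_subset=None,
                               gamma_metric: str = "ic") -> SemanticSimMatrix:
    """Pairwise SS over ``term_subset`` (default: every non-virtual term).

    The diagonal comes from the same formula: 1 for leaves,
    alpha/(alpha+beta) for internal terms.
    """
    if term_subset is None:
        terms = dag.term_ids
    else:
        terms = list(term_subset)
        missing = [t for t in terms if t not in dag]
        if missing:
            raise UnknownTermError(f"terms not in DAG: {missing}")
    n = len(terms)
    # Pre-compute per-term ancestor sets, MILs and beta halves once.
    anc = {t: ancestors(dag, t) for t in terms}
    mil = {t: find_mil(dag, ic_table, t) for t in terms}
    half_beta = {t: ic_distance(ic_table, t, mil[t]) for t in terms}
    values = np.zeros((n, n))
    for i, a in enumerate(terms):
        for j in range(i, n):
            b = terms[j]
            common = anc[a] & anc[b]
            mica = _most_informative(common, ic_table)
            alpha = ic_table[mica]
            if alpha == 0.0:
                ss = 0.0
            else:
                beta = (half_beta[a] + half_beta[b]) / 2.0
                if gamma_metric == "ic":
                    gamma = ic_distance(ic_table, mica, a) + ic_distance(ic_table, mica, b)
                else:
                    gamma = float(
                        nx.shortest_path_length(dag.graph, mica, a)
                        + nx.shortest_path_length(dag.graph, mica, b)
                    )
                ss = (alpha / (alpha + beta)) * (1.0 / (1.0 + gamma))
            values[i, j] = values[j, i] = ss
    return SemanticSimMatrix(labels=terms, values=values)
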