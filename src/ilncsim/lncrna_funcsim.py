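"""Group-based lncRNA functional similarity.

Each lncRNA *i* is represented by its disease group G(i) — the set of
diseases it is known to be associated with. The similarity of a disease *d*
to a group is its best match, ``SdG(d, G) = max_{d' in G} SS(d, d')``; the
directed group similarity sums best matches over one group's members, and
the functional similarity symmetrizes:

    FS(i, j) = (S_i->j + S_j->i) / (|G(i)| + |G(j)|)

FS lies in [0, 1] because each best-match term is. Note the diagonal is NOT
forced to 1: FS(i, i) = mean over G(i) of SS(d, d), which is below 1 as soon
as a non-leaf disease belongs to the group. ``unit_diagonal=True``
overwrites the diagonal with 1 for downstream predictors that expect it.
"""

from __future__ import annotations

import warnings

import numpy as np

from .association_data import AssociationTable
from .exceptions import IlncsimError, UnknownTermError
from .matrix import SquareLabeledMatrix


class EmptyGroupError(IlncsimError):
    """A disease group with no members entered a similarity computation."""


class FunctionalSimMatrix(SquareLabeledMatrix):
    """Symmetric lncRNA-lncRNA functional similarity, entries in [0, 1]."""

    #: lncRNAs dropped because no associated disease resolved in the DAG
    dropped: list[str]


def _positions(ss_matrix, diseases) -> list[int]:
    try:
        return [ss_matrix.position(d) for d in diseases]
    except KeyError as exc:
        raise UnknownTermError(f"disease {exc.args[0]!r} not in similarity matrix") from None


def best_match(ss_matrix, disease: str, group) -> float:
    """SdG(d, G): highest semantic similarity between ``disease`` and any group member."""
    group = list(group)
    if not group:
        raise EmptyGroupError("best_match against an empty disease group")
    i = _positions(ss_matrix, [disease])[0]
    cols = _positions(ss_matrix, group)
    return float(np.max(ss_matrix.values[i, cols]))


def group_similarity(ss_matrix, group_i, group_j) -> float:
    """Directed sum S_{i->j} of best matches of G(i)'s members in G(j)."""
    group_i, group_j = list(group_i), list(group_j)
    if not group_i or not group_j:
        raise EmptyGroupError("group_similarity with an empty disease group")
    rows = _positions(ss_matrix, group_i)
    cols = _positions(ss_matrix, group_j)
    sub = ss_matrix.values[np.ix_(rows, cols)]
    return float(sub.max(axis=1).sum())


def functional_similarity(ss_matrix, group_i, group_j) -> float:
    """Symmetrized FS(i, j) in [0, 1]."""
    s_ij = group_similarity(ss_matrix, group_i, group_j)
    s_ji = group_similarity(ss_matrix, group_j, group_i)
    return (s_ij + s_ji) / (len(set(group_i)) + len(set(group_j)))


def functional_similarity_matrix(ss_matrix, association_table: AssociationTable | dict,
                                 unit_diagonal: bool = False,
                                 on_empty: str = "error") -> FunctionalSimMatrix:
    """Pairwise FS over every lncRNA in the table.

    ``association_table`` may also be a precomputed ``{lncrna: set(diseases)}``
    mapping. lncRNAs whose group has no disease present in ``ss_matrix`` are
    dropped and listed on the result (``.dropped``); ``on_empty="zero"``
    instead keeps them with an all-zero row, which pipeline code uses when a
    cross-validation fold empties a group.
    """
    if isinstance(association_table, dict):
        groups = {k: set(v) for k, v in association_table.items()}
    else:
        groups = association_table.groups()
    known = set(ss_matrix.labels)
    resolved: dict[str, set[str]] = {}
    dropped: list[str] = []
    for lnc in sorted(groups):
        g = groups[lnc] & known
        if g:
            resolved[lnc] = g
        elif on_empty == "zero":
            resolved[lnc] = set()
        else:
            dropped.append(lnc)
    if dropped:
        warnings.warn(
            f"{len(dropped)} lncRNA(s) dropped: no associated disease in the "
            f"similarity matrix ({dropped[:5]}...)", stacklevel=2,
        )
    lncs = sorted(resolved)
    n = len(lncs)
    # cache row positions per group once
    pos = {lnc: _positions(ss_matrix, sorted(resolved[lnc])) for lnc in lncs}
    values = np.zeros((n, n))
    for a in range(n):
        pa = pos[lncs[a]]
        for b in range(a, n):
            pb = pos[lncs[b]]
            if not pa or not pb:
                fs = 0.0
            else:
                sub = ss_matrix.values[np.ix_(pa, pb)]
                fs = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (len(pa) + len(pb))
            values[a, b] = values[b, a] = fs
    if unit_diagonal:
        np.fill_diagonal(values, 1.0)
    out = FunctionalSimMatrix(labels=lncs, values=values)
    out.dropped = dropped
    return out
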