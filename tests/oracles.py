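"""Independent brute-force oracles used only by the test suite.

Everything here works from a raw parent->child edge list with plain dicts,
sets and recursion — deliberately sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import math


def edge_dicts(edges):
    children: dict[str, set[str]] = {}
    parents: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for p, c in edges:
        children.setdefault(p, set()).add(c)
        parents.setdefault(c, set()).add(p)
        nodes.update((p, c))
    return nodes, children, parents


def ancestors_bf(edges, node, inclusive=True):
    """All nodes with a directed path to ``node``, by exhaustive upward walk."""
    _, _, parents = edge_dicts(edges)
    out: set[str] = set()
    stack = list(parents.get(node, ()))
    while stack:
        u = stack.pop()
        if u not in out:
            out.add(u)
            stack.extend(parents.get(u, ()))
    if inclusive:
        out.add(node)
    return out


def descendants_bf(edges, node, inclusive=True):
    _, children, _ = edge_dicts(edges)
    out: set[str] = set()
    stack = list(children.get(node, ()))
    while stack:
        u = stack.pop()
        if u not in out:
            out.add(u)
            stack.extend(children.get(u, ()))
    if inclusive:
        out.add(node)
    return out


def leaves_under_bf(edges, node):
    _, children, _ = edge_dicts(edges)
    return {d for d in descendants_bf(edges, node) if not children.get(d)}


def structural_ic_bf(edges, root):
    """IC by hand: inclusive-descendant count over term count, p(root)=1."""
    nodes, _, _ = edge_dicts(edges)
    n = len(nodes)
    ic = {}
    for t in nodes:
        p = len(descendants_bf(edges, t)) / n
        ic[t] = 0.0 if t == root else -math.log(p)
    return ic


def semantic_similarity_bf(edges, root, a, b, ic=None):
    """SS by exhaustive MICA/MIL search over path-enumerated ancestor sets."""
    ic = ic or structural_ic_bf(edges, root)
    common = ancestors_bf(edges, a) & ancestors_bf(edges, b)
    mica = sorted(common, key=lambda t: (-ic[t], t))[0]
    alpha = ic[mica]
    if alpha == 0.0:
        return 0.0

    def half_beta(x):
        leaves = leaves_under_bf(edges, x)
        mil = sorted(leaves, key=lambda t: (-ic[t], t))[0]
        return abs(ic[x] - ic[mil])

    beta = (half_beta(a) + half_beta(b)) / 2.0
    gamma = abs(ic[mica] - ic[a]) + abs(ic[mica] - ic[b])
    return (alpha / (alpha + beta)) * (1.0 / (1.0 + gamma))


def semantic_similarity_matrix_bf(edges, root, terms):
    """Full SS matrix by brute force, with the per-term ancestor/leaf sets
    enumerated once up front (same exhaustive search, just not re-walked per
    pair so large sweeps stay fast)."""
    ic = structural_ic_bf(edges, root)
    anc = {t: ancestors_bf(edges, t) for t in terms}

    def mil_dist(x):
        leaves = leaves_under_bf(edges, x)
        mil = sorted(leaves, key=lambda t: (-ic[t], t))[0]
        return abs(ic[x] - ic[mil])

    hb = {t: mil_dist(t) for t in terms}
    out = {}
    for a in terms:
        for b in terms:
            common = anc[a] & anc[b]
            mica = sorted(common, key=lambda t: (-ic[t], t))[0]
            alpha = ic[mica]
            if alpha == 0.0:
                out[(a, b)] = 0.0
                continue
            beta = (hb[a] + hb[b]) / 2.0
            gamma = abs(ic[mica] - ic[a]) + abs(ic[mica] - ic[b])
            out[(a, b)] = (alpha / (alpha + beta)) * (1.0 / (1.0 + gamma))
    return out


def functional_similarity_bf(ss_lookup, group_i, group_j):
    """FS by explicit double loop; ``ss_lookup(a, b)`` returns SS."""
    def best(d, group):
        return max(ss_lookup(d, g) for g in group)

    s_ij = sum(best(d, group_j) for d in group_i)
    s_ji = sum(best(d, group_i) for d in group_j)
    return (s_ij + s_ji) / (len(group_i) + len(group_j))


def auc_pair_counting(scores, labels):
    """AUC by enumerating every positive/negative pair: (wins + 0.5*ties) / (n+ * n-)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
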