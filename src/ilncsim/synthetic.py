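"""Synthetic disease hierarchies and association tables with planted signal.

The DAG generator emulates the shape of a disease vocabulary hierarchy: a
rooted, mostly tree-like graph of bounded depth where some terms carry a
second parent (MeSH descriptors frequently sit in several branches). The
association generator realizes the core modeling assumption — lncRNAs with
similar function tend to associate with similar diseases — by partitioning
lncRNAs into modules and anchoring each module's diseases under a shared
internal ancestor. Anchoring at an ancestor (rather than an arbitrary
disease subset) is deliberate: it makes the planted signal visible to the
*semantic* similarity, not merely to co-annotation, so recovering it
exercises the whole similarity chain.

Everything is driven by a single integer seed through one ``numpy``
Generator, and iteration is over sorted identifiers, so outputs are
byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association_data import AssociationRecord, AssociationTable
from .dag_core import DiseaseDAG, build_dag_from_edges, descendants, leaves_under


@dataclass(frozen=True)
class DagGenParams:
    """Shape controls for the synthetic disease hierarchy."""

    n_terms: int = 40
    max_depth: int = 5
    branching_mean: float = 2.5
    multi_parent_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be at least 2")
        if self.n_terms < self.max_depth:
            raise ValueError("infeasible: n_terms < max_depth")
        if not 0.0 <= self.multi_parent_prob < 1.0:
            raise ValueError("multi_parent_prob must lie in [0, 1)")
        if self.branching_mean <= 0:
            raise ValueError("branching_mean must be positive")


@dataclass(frozen=True)
class AssocGenParams:
    """Planted-module association model parameters."""

    n_lncrnas: int = 24
    n_modules: int = 3
    diseases_per_module: int = 5
    within_module_assoc_prob: float = 0.6
    noise_assoc_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lncrnas", "n_modules", "diseases_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.within_module_assoc_prob <= 1.0:
            raise ValueError("within_module_assoc_prob must lie in (0, 1]")
        if not 0.0 <= self.noise_assoc_prob < 1.0:
            raise ValueError("noise_assoc_prob must lie in [0, 1)")
        if self.within_module_assoc_prob <= self.noise_assoc_prob:
            raise ValueError("planted signal requires within_module_assoc_prob > noise_assoc_prob")


@dataclass
class SyntheticAssociations:
    """Generated table plus the ground truth used to plant it."""

    table: AssociationTable
    lncrna_modules: dict[str, int]
    module_diseases: dict[int, list[str]]


def generate_dag(params: DagGenParams) -> DiseaseDAG:
    """Random rooted DAG: tree grown under a depth cap, then extra parents.

    Parents are chosen with weight ``branching_mean / (branching_mean +
    current child count)``, giving a mean out-degree near ``branching_mean``
    without hard caps. Extra parents are sampled only among non-descendants,
    so acyclicity holds by construction.
    """
    rng = np.random.default_rng(params.seed)
    ids = [f"D{k:03d}" for k in range(params.n_terms)]
    depth = {ids[0]: 0}
    children: dict[str, int] = {ids[0]: 0}
    edges: list[tuple[str, str]] = []
    for k in range(1, params.n_terms):
        candidates = [t for t in ids[:k] if depth[t] < params.max_depth]
        if not candidates:
            raise ValueError("depth cap leaves no eligible parents; loosen max_depth")
        weights = np.array([params.branching_mean / (params.branching_mean + children[t])
                            for t in candidates])
        parent = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
        edges.append((parent, ids[k]))
        depth[ids[k]] = depth[parent] + 1
        children[parent] += 1
        children[ids[k]] = 0
    # second parents: sample only among current non-descendants, so each
    # added edge keeps the working graph acyclic
    import networkx as nx

    work = nx.DiGraph(edges)
    for node in ids[1:]:
        if rng.random() >= params.multi_parent_prob:
            continue
        blocked = nx.descendants(work, node) | set(work.predecessors(node)) | {node}
        pool = [t for t in ids if t not in blocked]
        if pool:
            work.add_edge(pool[rng.integers(len(pool))], node)
    return build_dag_from_edges(sorted(work.edges))


def _module_anchors(dag: DiseaseDAG, params: AssocGenParams,
                    rng: np.random.Generator) -> dict[int, list[str]]:
    """Pick one internal anchor per module and sample its disease neighborhood."""
    anchors = []
    for t in dag.term_ids:
        if t == dag.root or dag.is_leaf(t):
            continue
        pool = sorted(descendants(dag, t) - {t, dag.root})
        if len(pool) >= params.diseases_per_module:
            anchors.append((t, pool))
    rng.shuffle(anchors)
    module_diseases: dict[int, list[str]] = {}
    used: set[str] = set()
    for m in range(params.n_modules):
        placed = False
        for a_idx, (anchor, pool) in enumerate(anchors):
            fresh = [d for d in pool if d not in used]
            if len(fresh) < params.diseases_per_module:
                continue
            leaves = sorted(leaves_under(dag, anchor) - used)
            # prefer leaf terms; pad with internal descendants if needed
            chosen = [str(x) for x in
                      rng.choice(leaves, size=min(len(leaves), params.diseases_per_module),
                                 replace=False)]
            others = [d for d in fresh if d not in set(chosen)]
            while len(chosen) < params.diseases_per_module:
                chosen.append(others.pop(rng.integers(len(others))))
            module_diseases[m] = sorted(chosen)
            used.update(chosen)
            anchors.pop(a_idx)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"infeasible partition: cannot place module {m} "
                f"({params.diseases_per_module} diseases per module on a "
                f"{dag.n_terms}-term DAG)"
            )
    return module_diseases


def generate_associations(dag: DiseaseDAG, params: AssocGenParams) -> SyntheticAssociations:
    """Plant block-structured lncRNA-disease associations on the DAG.

    Within-module pairs associate with ``within_module_assoc_prob``; every
    (lncRNA, disease) pair over the pooled module diseases additionally
    associates with ``noise_assoc_prob``. lncRNAs left with no association
    receive one uniformly drawn disease from their module.
    """
    rng = np.random.default_rng(params.seed)
    module_diseases = _module_anchors(dag, params, rng)
    all_diseases = sorted({d for ds in module_diseases.values() for d in ds})
    lncs = [f"L{k:03d}" for k in range(params.n_lncrnas)]
    lnc_module = {lnc: k % params.n_modules for k, lnc in enumerate(lncs)}
    pairs: set[tuple[str, str]] = set()
    for lnc in lncs:
        m = lnc_module[lnc]
        for d in module_diseases[m]:
            if rng.random() < params.within_module_assoc_prob:
                pairs.add((lnc, d))
        for d in all_diseases:
            if rng.random() < params.noise_assoc_prob:
                pairs.add((lnc, d))
        if not any(p[0] == lnc for p in pairs):
            ds = module_diseases[m]
            pairs.add((lnc, ds[rng.integers(len(ds))]))
    records = [AssociationRecord(lnc, dis) for lnc, dis in sorted(pairs)]
    table = AssociationTable(records=records)
    return SyntheticAssociations(table=table, lncrna_modules=lnc_module,
                                 module_diseases=module_diseases)


def shuffle_associations(table: AssociationTable, seed: int) -> AssociationTable:
    """Permutation null: re-pair lncRNAs and diseases at random.

    The disease column is permuted across records (marginal counts are
    approximately preserved); duplicate pairs created by the shuffle
    collapse. Destroys any real structure linking groups to similarity.
    """
    rng = np.random.default_rng(seed)
    lncs = [r.lncrna for r in table.records]
    diseases = [r.disease for r in table.records]
    perm = rng.permutation(len(diseases))
    pairs = sorted({(lncs[i], diseases[perm[i]]) for i in range(len(lncs))})
    return AssociationTable(records=[AssociationRecord(l, d) for l, d in pairs],
                            display_names=dict(table.display_names))
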