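"""Disease DAG construction and per-term information content.

The disease hierarchy is a rooted directed acyclic graph (edges point from
parent to child). It is built either from MeSH descriptor files — Category C
tree numbers encode the hierarchy: a descriptor with tree number
``C04.557.337`` is a child of whichever descriptor holds ``C04.557`` — or
from an explicit parent/child edge list. Multi-parenting is allowed: a
descriptor with tree numbers in several branches has several parents.

Information content quantifies term specificity: ``IC(t) = -log p(t)`` in
nats, with ``p(root) = 1`` so the root carries no information. Two choices
of ``p`` are offered:

* ``structural`` (default): ``p(t)`` is the fraction of terms at or below
  ``t``, which makes the model self-contained — no annotation corpus needed.
* ``annotation``: ``p(t)`` is the (add-one smoothed) fraction of
  associations annotated to ``t`` or any descendant.

Both are monotone: IC never decreases walking away from the root, which is
what guarantees the non-negativity of the downstream similarity components.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

from .exceptions import GraphError, InputFormatError, UnknownTermError

#: Identifier of the virtual root inserted when a hierarchy has several
#: top-level terms (MeSH Category C has many: C01, C04, ...). Chosen to be
#: an invalid MeSH UI so it cannot collide with real descriptors.
VIRTUAL_ROOT = "<ROOT>"


@dataclass(frozen=True)
class DiseaseTerm:
    """A node of the disease hierarchy.

    ``tree_numbers`` is empty for DAGs built from plain edge lists.
    """

    term_id: str
    name: str = ""
    tree_numbers: tuple[str, ...] = ()


@dataclass
class DiseaseDAG:
    """Rooted DAG of disease terms; ``graph`` edges run parent -> child."""

    graph: nx.DiGraph
    root: str
    terms: dict[str, DiseaseTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid in self.graph.nodes:
            self.terms.setdefault(tid, DiseaseTerm(term_id=tid))
        _validate(self.graph, self.root)

    # -- basic queries ----------------------------------------------------
    @property
    def term_ids(self) -> list[str]:
        """All term identifiers except the virtual root, sorted."""
        return sorted(t for t in self.graph.nodes if t != VIRTUAL_ROOT)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def is_leaf(self, term_id: str) -> bool:
        self._require(term_id)
        return self.graph.out_degree(term_id) == 0

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id].name if term_id in self.terms else ""

    def _require(self, term_id: str) -> None:
        if term_id not in self.graph:
            raise UnknownTermError(f"unknown disease term: {term_id!r}")


@dataclass
class ICTable:
    """Per-term probability ``p`` and information content ``ic = -log p`` (nats)."""

    ic: dict[str, float]
    p: dict[str, float]
    method: str = "structural"

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.ic[term_id]
        except KeyError:
            raise UnknownTermError(f"term {term_id!r} has no information content") from None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic


def _validate(graph: nx.DiGraph, root: str) -> None:
    if root not in graph:
        raise GraphError(f"declared root {root!r} is not a node of the graph")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise GraphError(f"disease graph contains a cycle: {cycle}")
    reachable = {root} | nx.descendants(graph, root)
    unreachable = set(graph.nodes) - reachable
    if unreachable:
        raise GraphError(
            f"{len(unreachable)} terms unreachable from root {root!r}: "
            f"{sorted(unreachable)[:5]}..."
        )


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def build_dag_from_edges(
    edge_list: Iterable[tuple[str, str]],
    nodes: Iterable[str] = (),
    names: Mapping[str, str] | None = None,
) -> DiseaseDAG:
    """Build a DAG from explicit (parent_id, child_id) pairs.

    Parentless nodes become children of a single virtual root; when exactly
    one parentless node exists it simply is the root (no virtual node is
    inserted). Duplicate edges are dropped with a warning; a cycle is an
    error naming one offending cycle.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    seen: set[tuple[str, str]] = set()
    dupes = 0
    for parent, child in edge_list:
        if (parent, child) in seen:
            dupes += 1
            continue
        seen.add((parent, child))
        graph.add_edge(parent, child)
    if dupes:
        warnings.warn(f"{dupes} duplicate edge(s) dropped", stacklevel=2)
    if graph.number_of_nodes() == 0:
        raise GraphError("empty edge list and no nodes given")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise GraphError(f"edge list contains a cycle: {cycle}")
    top = sorted(n for n in graph.nodes if graph.in_degree(n) == 0)
    if not top:
        raise GraphError("no parentless node found (cyclic input?)")
    if len(top) == 1:
        root = top[0]
    else:
        root = VIRTUAL_ROOT
        for t in top:
            graph.add_edge(root, t)
    terms = {}
    if names:
        for tid, name in names.items():
            terms[tid] = DiseaseTerm(term_id=tid, name=name)
    return DiseaseDAG(graph=graph, root=root, terms=terms)


def _parse_mesh_ascii(text: str) -> list[DiseaseTerm]:
    records = [r for r in text.split("*NEWRECORD") if r.strip()]
    out = []
    for idx, rec in enumerate(records):
        name = ui = None
        tree_numbers: list[str] = []
        for line in rec.splitlines():
            line = line.strip()
            if line.startswith("MH = "):
                name = line[5:].strip()
            elif line.startswith("UI = "):
                ui = line[5:].strip()
            elif line.startswith("MN = "):
                tree_numbers.append(line[5:].strip())
        if not ui or not name:
            raise InputFormatError(
                f"malformed MeSH record #{idx}: missing {'UI' if not ui else 'MH'} field"
            )
        out.append(DiseaseTerm(term_id=ui, name=name, tree_numbers=tuple(tree_numbers)))
    return out


def _parse_mesh_xml(text: str) -> list[DiseaseTerm]:
    import xml.etree.ElementTree as ET

    root = ET.fromstring(text)
    out = []
    for idx, rec in enumerate(root.iter("DescriptorRecord")):
        ui_el = rec.find("DescriptorUI")
        name_el = rec.find("DescriptorName/String")
        if ui_el is None or not (ui_el.text or "").strip():
            raise InputFormatError(f"malformed MeSH XML record #{idx}: missing DescriptorUI")
        if name_el is None or not (name_el.text or "").strip():
            raise InputFormatError(f"malformed MeSH XML record #{idx}: missing DescriptorName")
        tns = tuple(
            (tn.text or "").strip()
            for tn in rec.iter("TreeNumber")
            if (tn.text or "").strip()
        )
        out.append(
            DiseaseTerm(term_id=ui_el.text.strip(), name=name_el.text.strip(), tree_numbers=tns)
        )
    return out


def parse_mesh_descriptors(descriptor_stream: str | os.PathLike | IO[str],
                           category_prefix: str = "C") -> DiseaseDAG:
    """Parse a MeSH descriptor file (ASCII ``d20XX.bin`` or XML ``desc20XX.xml``).

    Keeps descriptors having at least one tree number under
    ``category_prefix``; edges follow tree-number nesting (one extra
    dot-separated segment = one parent/child step). Top-level branch heads
    hang off a single virtual root.
    """
    if hasattr(descriptor_stream, "read"):
        text = descriptor_stream.read()
    else:
        with open(descriptor_stream, "r", encoding="utf-8") as fh:
            text = fh.read()
    dialect_xml = text.lstrip()[:1] == "<"
    records = _parse_mesh_xml(text) if dialect_xml else _parse_mesh_ascii(text)

    def in_category(tn: str) -> bool:
        head = tn.split(".", 1)[0]
        return head == category_prefix or head.startswith(category_prefix)

    kept = []
    for term in records:
        tns = tuple(tn for tn in term.tree_numbers if in_category(tn))
        if tns:
            kept.append(DiseaseTerm(term_id=term.term_id, name=term.name, tree_numbers=tns))
    if not kept:
        raise InputFormatError(
            f"no descriptors with tree numbers under category {category_prefix!r}"
        )

    tn_owner: dict[str, str] = {}
    for term in kept:
        for tn in term.tree_numbers:
            tn_owner[tn] = term.term_id

    graph = nx.DiGraph()
    graph.add_node(VIRTUAL_ROOT)
    for term in kept:
        graph.add_node(term.term_id)
    for term in kept:
        for tn in term.tree_numbers:
            if "." in tn:
                parent_tn = tn.rsplit(".", 1)[0]
                if parent_tn in tn_owner:
                    graph.add_edge(tn_owner[parent_tn], term.term_id)
                else:
                    # orphaned branch (parent descriptor outside the file)
                    graph.add_edge(VIRTUAL_ROOT, term.term_id)
            else:
                graph.add_edge(VIRTUAL_ROOT, term.term_id)
    if not nx.is_directed_acyclic_graph(graph):
        raise InputFormatError("tree numbers induce a cyclic graph; corrupt descriptor file")
    terms = {t.term_id: t for t in kept}
    return DiseaseDAG(graph=graph, root=VIRTUAL_ROOT, terms=terms)


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def ancestors(dag: DiseaseDAG, term_id: str, inclusive: bool = True) -> set[str]:
    """All terms with a directed path down to ``term_id`` (itself included by default)."""
    dag._require(term_id)
    anc = nx.ancestors(dag.graph, term_id)
    if inclusive:
        anc = anc | {term_id}
    return anc


def descendants(dag: DiseaseDAG, term_id: str, inclusive: bool = True) -> set[str]:
    dag._require(term_id)
    dec = nx.descendants(dag.graph, term_id)
    if inclusive:
        dec = dec | {term_id}
    return dec


def leaves_under(dag: DiseaseDAG, term_id: str) -> set[str]:
    """Leaf descendants of a term; a leaf yields the singleton of itself."""
    dag._require(term_id)
    return {t for t in descendants(dag, term_id) if dag.graph.out_degree(t) == 0}


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

def compute_ic(dag: DiseaseDAG, method: str = "structural",
               associations=None) -> ICTable:
    """Compute ``IC(t) = -log p(t)`` for every term (natural log, nats).

    ``structural``: p(t) = |inclusive descendants of t| / |terms|, the term
    count excluding any virtual root; p(root) is forced to 1.
    ``annotation``: p(t) = (associations on t or below + 1) / (total + 1);
    requires an association table mapped to this DAG.
    """
    if dag.n_terms == 0:
        raise GraphError("cannot compute information content of an empty DAG")
    p: dict[str, float] = {}
    if method == "structural":
        n = dag.n_terms
        for t in dag.graph.nodes:
            count = len(descendants(dag, t) - {VIRTUAL_ROOT})
            p[t] = count / n
    elif method == "annotation":
        if associations is None:
            raise ValueError("annotation IC requires an association table")
        counts: dict[str, int] = {}
        for rec in associations.records:
            counts[rec.disease] = counts.get(rec.disease, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("annotation IC requires at least one association")
        for t in dag.graph.nodes:
            below = sum(counts.get(d, 0) for d in descendants(dag, t))
            p[t] = (below + 1) / (total + 1)
    else:
        raise ValueError(f"unknown IC method {method!r} (expected 'structural' or 'annotation')")
    p[dag.root] = 1.0
    ic = {t: -math.log(pt) for t, pt in p.items()}
    ic[dag.root] = 0.0
    return ICTable(ic=ic, p=p, method=method)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def read_edge_list(path_or_buf) -> list[tuple[str, str]]:
    """Read a 2-column TSV of (parent_id, child_id); '#' starts a comment line."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    edges = []
    for ln, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) < 2:
            raise InputFormatError(f"edge list line {ln}: expected 2 columns, got {line!r}")
        edges.append((parts[0], parts[1]))
    return edges


def write_dag(dag: DiseaseDAG, nodes_path, edges_path, ic_table: ICTable | None = None) -> None:
    """Export node table (term_id, name, ic) and edge table (parent, child) as TSV."""
    import pandas as pd

    rows = []
    for tid in dag.term_ids:
        rows.append(
            (tid, dag.name_of(tid), ic_table[tid] if ic_table is not None else float("nan"))
        )
    pd.DataFrame(rows, columns=["term_id", "name", "ic"]).to_csv(
        nodes_path, sep="\t", index=False
    )
    edges = sorted(dag.graph.edges)
    pd.DataFrame(edges, columns=["parent_id", "child_id"]).to_csv(
        edges_path, sep="\t", index=False
    )
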