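"""lncRNA-disease association tables.

Reads the flat two-or-three-column extracts that curated repositories such
as MNDR and Lnc2Cancer ship (lncRNA symbol, disease name, optional
evidence), normalizes and deduplicates them, resolves disease references
against a disease DAG, and produces the binary adjacency matrix the
predictor consumes.

Identity is case-insensitive (H19 and h19 are the same transcript) but the
first-seen spelling is kept for display. Disease references are resolved by
exact case-insensitive match on term id or term name only — no fuzzy
matching; unmatched records are reported, never guessed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dag_core import DiseaseDAG, VIRTUAL_ROOT
from .exceptions import InputFormatError


class AssociationRecord(NamedTuple):
    lncrna: str
    disease: str
    evidence: str | None = None


@dataclass
class AssociationTable:
    """Deduplicated lncRNA-disease association records.

    ``lncrna_index`` / ``disease_index`` are the sorted unique identifiers;
    they define row/column order everywhere downstream.
    """

    records: list[AssociationRecord]
    n_duplicates_removed: int = 0
    display_names: dict[str, str] = field(default_factory=dict)

    @property
    def lncrna_index(self) -> list[str]:
        return sorted({r.lncrna for r in self.records})

    @property
    def disease_index(self) -> list[str]:
        return sorted({r.disease for r in self.records})

    def groups(self) -> dict[str, set[str]]:
        """Disease group G(i): the set of diseases associated with each lncRNA."""
        out: dict[str, set[str]] = {}
        for rec in self.records:
            out.setdefault(rec.lncrna, set()).add(rec.disease)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def display(self, key: str) -> str:
        return self.display_names.get(key, key)


@dataclass
class AdjacencyMatrix:
    """Binary known-association profile Y: rows lncRNAs, columns diseases."""

    lncrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValueError("adjacency shape does not match index lengths")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")

    def to_tsv(self, path_or_buf) -> None:
        pd.DataFrame(self.values, index=self.lncrna_ids,
                     columns=self.disease_ids).to_csv(path_or_buf, sep="\t", index_label="")


def _norm(s: str) -> str:
    return s.strip().casefold()


def read_associations(path_or_buf, dialect: str | None = None,
                      lncrna_col: int = 0, disease_col: int = 1,
                      evidence_col: int | None = 2) -> AssociationTable:
    """Read a TSV/CSV association table; header row auto-detected.

    Rows are whitespace-trimmed, identity is case-folded, and exact
    duplicate (lncRNA, disease) pairs are dropped (the removed count is kept
    on the table).
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            text = fh.read()
    sep = {"tsv": "\t", "csv": ","}.get(dialect or "")
    if sep is None:
        first = text.splitlines()[0] if text.splitlines() else ""
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise InputFormatError(
            f"association table needs at least 2 columns, found {df.shape[1]}"
        )
    # Header heuristic: the first row is a header iff a cell equals a known
    # column name (exact match after lowercasing/stripping separators), so
    # symbols like "lincRNA-p21" in data rows are never mistaken for headers.
    header_tokens = {"lncrna", "lncrnaid", "lncrnaname", "lncrnasymbol", "ncrna",
                     "disease", "diseaseid", "diseasename", "diseaseterm",
                     "evidence", "pmid", "reference", "source"}
    first_row = ["".join(ch for ch in str(x).casefold() if ch.isalnum())
                 for x in df.iloc[0]]
    if any(c in header_tokens for c in first_row):
        df = df.iloc[1:]
    if df.empty:
        raise InputFormatError("association table is empty")

    display: dict[str, str] = {}
    seen: set[tuple[str, str]] = set()
    records: list[AssociationRecord] = []
    dupes = 0
    for _, row in df.iterrows():
        lnc_raw = str(row.iloc[lncrna_col]).strip()
        dis_raw = str(row.iloc[disease_col]).strip()
        if not lnc_raw or not dis_raw or lnc_raw == "nan" or dis_raw == "nan":
            continue
        ev = None
        if evidence_col is not None and evidence_col < df.shape[1]:
            v = row.iloc[evidence_col]
            ev = None if pd.isna(v) else str(v).strip()
        lnc, dis = _norm(lnc_raw), _norm(dis_raw)
        display.setdefault(lnc, lnc_raw)
        display.setdefault(dis, dis_raw)
        if (lnc, dis) in seen:
            dupes += 1
            continue
        seen.add((lnc, dis))
        records.append(AssociationRecord(lnc, dis, ev))
    if not records:
        raise InputFormatError("association table is empty after filtering")
    return AssociationTable(records=records, n_duplicates_removed=dupes,
                            display_names=display)


def map_to_dag(table: AssociationTable, dag: DiseaseDAG
               ) -> tuple[AssociationTable, list[AssociationRecord]]:
    """Resolve disease references to DAG term ids.

    Exact case-insensitive match on term_id or term name. Unmatched records
    are removed and returned as the report (not an error); records mapping
    to the same (lncRNA, term) pair collapse to one.
    """
    lookup: dict[str, str] = {}
    for tid, term in dag.terms.items():
        if tid == VIRTUAL_ROOT:
            continue
        lookup.setdefault(_norm(tid), tid)
        if term.name:
            lookup.setdefault(_norm(term.name), tid)

    mapped: list[AssociationRecord] = []
    unmapped: list[AssociationRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in table.records:
        tid = lookup.get(_norm(rec.disease))
        if tid is None:
            unmapped.append(rec)
            continue
        if (rec.lncrna, tid) in seen:
            continue
        seen.add((rec.lncrna, tid))
        mapped.append(AssociationRecord(rec.lncrna, tid, rec.evidence))
    out = AssociationTable(records=mapped,
                           n_duplicates_removed=table.n_duplicates_removed,
                           display_names=dict(table.display_names))
    return out, unmapped


def to_matrix(table: AssociationTable) -> AdjacencyMatrix:
    """Binary adjacency with sorted, deterministic row/column order."""
    if not table.records:
        raise InputFormatError("cannot build adjacency from an empty table")
    lncs = table.lncrna_index
    diss = table.disease_index
    li = {x: i for i, x in enumerate(lncs)}
    di = {x: j for j, x in enumerate(diss)}
    values = np.zeros((len(lncs), len(diss)), dtype=np.int8)
    for rec in table.records:
        values[li[rec.lncrna], di[rec.disease]] = 1
    return AdjacencyMatrix(lncrna_ids=lncs, disease_ids=diss, values=values)


def write_associations(table: AssociationTable, path_or_buf) -> None:
    rows = [(table.display(r.lncrna), table.display(r.disease), r.evidence or "")
            for r in table.records]
    pd.DataFrame(rows, columns=["lncrna_id", "disease", "evidence"]).to_csv(
        path_or_buf, sep="\t", index=False
    )
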