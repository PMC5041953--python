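"""Labeled dense matrices with plain-text (TSV) round-trip I/O.

Similarity and score matrices throughout the package are small and dense
(hundreds of diseases / lncRNAs), so a numpy array plus ordered label lists
is the right container; pandas handles serialization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledMatrix:
    """A dense real matrix with row and column labels.

    ``index`` maps are derived, so construct via the dataclass fields and
    look entries up with :meth:`loc`.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        self._row_index = {t: i for i, t in enumerate(self.row_labels)}
        self._col_index = {t: i for i, t in enumerate(self.col_labels)}

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self._row_index[row], self._col_index[col]])

    def row_position(self, label: str) -> int:
        return self._row_index[label]

    def col_position(self, label: str) -> int:
        return self._col_index[label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "LabeledMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
        return cls(
            row_labels=[str(x) for x in df.index],
            col_labels=[str(x) for x in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class SquareLabeledMatrix(LabeledMatrix):
    """Symmetric similarity matrix over a single entity set."""

    def __init__(self, labels: list[str], values: np.ndarray):
        super().__init__(row_labels=list(labels), col_labels=list(labels), values=values)

    @property
    def labels(self) -> list[str]:
        return self.row_labels

    def position(self, label: str) -> int:
        return self._row_index[label]

    def to_long_tsv(self, path_or_buf, value_name: str = "similarity") -> None:
        """Three-column long format: entity_a, entity_b, value (upper triangle incl. diagonal)."""
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i, n):
                rows.append((self.labels[i], self.labels[j], self.values[i, j]))
        pd.DataFrame(rows, columns=["term_a", "term_b", value_name]).to_csv(
            path_or_buf, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path_or_buf) -> "SquareLabeledMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
        labels = [str(x) for x in df.index]
        if labels != [str(x) for x in df.columns]:
            raise ValueError("square matrix TSV must have identical row and column labels")
        return cls(labels=labels, values=df.to_numpy(dtype=float))


def tsv_string(matrix: LabeledMatrix) -> str:
    buf = io.StringIO()
    matrix.to_tsv(buf)
    return buf.getvalue()
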