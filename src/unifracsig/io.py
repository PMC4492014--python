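"""Tip-by-sample abundance tables and their binding to a tree.

The table format is a UTF-8 TSV with header ``#TIP_ID<TAB>sample1<TAB>...``
(the leading ``#`` is optional), one row per tip, cells holding non-negative
integer occurrence counts.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tree import TreeNode, validate_tree


class TableError(ValueError):
    """Invalid abundance-table content."""


class BindingError(ValueError):
    """Table refers to tips that do not exist in the tree."""


class AbundanceTable:
    """Immutable tip x sample matrix of non-negative integer counts."""

    def __init__(self, tip_ids: Sequence[str], sample_ids: Sequence[str],
                 counts: Iterable):
        self.tip_ids = list(tip_ids)
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.tip_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.tip_ids)} tips x {len(self.sample_ids)} samples")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise TableError("counts must be integers")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise TableError("counts must be non-negative")
        if len(set(self.tip_ids)) != len(self.tip_ids):
            dup = next(t for t in self.tip_ids if self.tip_ids.count(t) > 1)
            raise TableError(f"duplicate tip row: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableError("duplicate sample id in header")
        counts.setflags(write=False)
        self.counts = counts
        self._tip_index = {t: i for i, t in enumerate(self.tip_ids)}

    # -- access ----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample: {sample_id!r}") from None

    def vector(self, tip_id: str) -> np.ndarray:
        return self.counts[self._tip_index[tip_id]]

    def total(self, sample_id: str) -> int:
        return int(self.counts[:, self.sample_index(sample_id)].sum())

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def __eq__(self, other) -> bool:
        return (isinstance(other, AbundanceTable)
                and self.tip_ids == other.tip_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_tsv(cls, text: str) -> "AbundanceTable":
        rows = list(csv.reader(_io.StringIO(text), delimiter="\t"))
        rows = [r for r in rows if r and any(cell.strip() for cell in r)]
        if not rows:
            raise TableError("empty table")
        header = [c.strip() for c in rows[0]]
        if header[0].startswith("#"):
            header[0] = header[0].lstrip("#")
        sample_ids = header[1:]
        if not sample_ids:
            raise TableError("header has no sample columns")
        tip_ids: list[str] = []
        counts = np.zeros((len(rows) - 1, len(sample_ids)), dtype=np.int64)
        for i, row in enumerate(rows[1:], start=1):
            if len(row) != len(header):
                raise TableError(f"row {i + 1} has {len(row)} fields, "
                                 f"expected {len(header)}")
            tip_ids.append(row[0].strip())
            for j, cell in enumerate(row[1:], start=1):
                try:
                    value = int(cell)
                except ValueError:
                    raise TableError(
                        f"non-integer count {cell!r} at row {i + 1}, "
                        f"column {j + 1}") from None
                if value < 0:
                    raise TableError(
                        f"negative count {value} at row {i + 1}, column {j + 1}")
                counts[i - 1, j - 1] = value
        return cls(tip_ids, sample_ids, counts)

    @classmethod
    def read(cls, path) -> "AbundanceTable":
        return cls.from_tsv(Path(path).read_text(encoding="utf-8"))

    def to_tsv(self) -> str:
        lines = ["#TIP_ID\t" + "\t".join(self.sample_ids)]
        for tip, row in zip(self.tip_ids, self.counts):
            lines.append(tip + "\t" + "\t".join(str(v) for v in row))
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_tsv(), encoding="utf-8")


@dataclass
class BoundDataset:
    """A tree and a table whose rows are exactly the tree's tips in tree order.

    Tree tips absent from the input table carry all-zero count vectors.
    """

    tree: TreeNode
    table: AbundanceTable

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    @property
    def tip_ids(self) -> list[str]:
        return self.table.tip_ids

    @property
    def counts(self) -> np.ndarray:
        return self.table.counts

    def copy(self) -> "BoundDataset":
        return BoundDataset(self.tree.copy(), self.table)

    def with_counts(self, counts: np.ndarray) -> "BoundDataset":
        """Same tree/tips/samples, different count matrix (shares the tree)."""
        return BoundDataset(
            self.tree, AbundanceTable(self.tip_ids, self.sample_ids, counts))


def bind(tree: TreeNode, table: AbundanceTable) -> BoundDataset:
    """Align a table to a tree's tips, zero-filling tips the table omits.

    Raises :class:`BindingError` naming every table row with no matching tip.
    """
    tip_order = tree.tip_names()
    known = set(tip_order)
    unmatched = [t for t in table.tip_ids if t not in known]
    if unmatched:
        raise BindingError(
            "table rows with no matching tree tip: "
            + ", ".join(repr(t) for t in unmatched))
    counts = np.zeros((len(tip_order), table.n_samples), dtype=np.int64)
    for i, tip in enumerate(tip_order):
        if tip in table._tip_index:
            counts[i] = table.vector(tip)
    return BoundDataset(tree, AbundanceTable(tip_order, table.sample_ids, counts))


def validate_dataset(ds: BoundDataset) -> None:
    """Check all BoundDataset invariants; raise on any violation."""
    validate_tree(ds.tree)
    if ds.tip_ids != ds.tree.tip_names():
        raise BindingError("table rows are not the tree tips in tree order")
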