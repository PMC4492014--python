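"""Unweighted and weighted UniFrac via a single post-order branch accumulation.

For two samples a, b with grand totals N(a), N(b), and per-branch descendant
count totals n_b(s) on branch lengths l_b (the root's own branch excluded):

unweighted
    U = sum(l_b : exactly one of n_b(a), n_b(b) > 0)
        / sum(l_b : at least one of n_b(a), n_b(b) > 0)

weighted (raw)
    W = sum_b l_b * | n_b(a)/N(a) - n_b(b)/N(b) |

weighted (normalized)
    W / D  with  D = sum_tips_j d_j * ( c_j(a)/N(a) + c_j(b)/N(b) ),
    d_j the root-to-tip path length and c_j(s) the tip's count.

Branches with no descendants in either compared sample contribute to nothing,
so the computation is restricted to the two samples under comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BoundDataset


class UniFracError(ValueError):
    pass


METRICS = ("unweighted", "weighted", "weighted-normalized")


class LinearizedDataset:
    """Flat array view of a bound dataset for repeated metric evaluation.

    Nodes are numbered in postorder (root last) so a single forward pass over
    ``parent_index`` accumulates tip counts up the tree.  Count matrices may
    carry arbitrary leading batch dimensions, which is what makes vectorized
    permutation testing cheap.
    """

    def __init__(self, ds: BoundDataset):
        nodes = list(ds.tree.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent_index = np.array(
            [index[id(n.parent)] if n.parent is not None else -1 for n in nodes],
            dtype=np.intp)
        self.node_lengths = np.array([n.length for n in nodes])
        tip_pos = {n.name: index[id(n)] for n in nodes if n.is_tip}
        self.tip_node_index = np.array([tip_pos[t] for t in ds.tip_ids],
                                       dtype=np.intp)
        depths = ds.tree.depths()
        by_id = {id(n): d for n, d in depths.items()}
        self.tip_depths = np.array([by_id[id(nodes[i])]
                                    for i in self.tip_node_index])
        # non-root branches in postorder; root is always the final node
        self.branch_lengths = self.node_lengths[:-1]
        self.sample_ids = list(ds.sample_ids)
        self.counts = ds.counts

    def branch_counts(self, tip_counts: np.ndarray) -> np.ndarray:
        """Per-branch descendant totals, shape ``(..., n_branches, n_samples)``."""
        tip_counts = np.asarray(tip_counts, dtype=float)
        batch = tip_counts.shape[:-2]
        n_samples = tip_counts.shape[-1]
        acc = np.zeros(batch + (self.n_nodes, n_samples))
        acc[..., self.tip_node_index, :] = tip_counts
        for i in range(self.n_nodes - 1):  # root (last) has no parent
            acc[..., self.parent_index[i], :] += acc[..., i, :]
        return acc[..., :-1, :]

    # -- batched metric kernels ------------------------------------------

    def unweighted(self, tip_counts: np.ndarray, ia: int, ib: int,
                   warn_on_empty: bool = True) -> np.ndarray:
        nb = self.branch_counts(tip_counts)
        in_a = nb[..., ia] > 0
        in_b = nb[..., ib] > 0
        l = self.branch_lengths
        shared = ((in_a | in_b) * l).sum(axis=-1)
        unique = ((in_a ^ in_b) * l).sum(axis=-1)
        out = np.divide(unique, shared, out=np.zeros_like(unique),
                        where=shared > 0)
        if warn_on_empty and np.any(shared == 0):
            warnings.warn("all branches covering the compared samples have "
                          "zero length; unweighted UniFrac defined as 0")
        return out

    def weighted(self, tip_counts: np.ndarray, ia: int, ib: int,
                 normalized: bool = False) -> np.ndarray:
        # a permutation (WITHIN_TIP_SWAP) may empty one sample; its relative
        # abundances are then all zero rather than 0/0.  The scalar API
        # validates totals up front and still rejects empty input samples.
        tip_counts = np.asarray(tip_counts, dtype=float)
        na_tot = tip_counts[..., ia].sum(axis=-1)[..., None]
        nb_tot = tip_counts[..., ib].sum(axis=-1)[..., None]
        pa = np.divide(tip_counts[..., ia], na_tot,
                       out=np.zeros_like(tip_counts[..., ia]),
                       where=na_tot > 0)
        pb = np.divide(tip_counts[..., ib], nb_tot,
                       out=np.zeros_like(tip_counts[..., ib]),
                       where=nb_tot > 0)
        nb = self.branch_counts(np.stack([pa, pb], axis=-1))
        diff = np.abs(nb[..., 0] - nb[..., 1])
        w = (self.branch_lengths * diff).sum(axis=-1)
        if not normalized:
            return w
        d = (self.tip_depths * (pa + pb)).sum(axis=-1)
        if np.any(d == 0):
            raise UniFracError("normalization denominator is zero "
                               "(all root-to-tip path lengths are zero)")
        return np.divide(w, d)

    def evaluate(self, tip_counts: np.ndarray, ia: int, ib: int,
                 metric: str, warn_on_empty: bool = True) -> np.ndarray:
        if metric == "unweighted":
            return self.unweighted(tip_counts, ia, ib, warn_on_empty)
        if metric == "weighted":
            return self.weighted(tip_counts, ia, ib, normalized=False)
        if metric == "weighted-normalized":
            return self.weighted(tip_counts, ia, ib, normalized=True)
        raise UniFracError(f"unknown metric {metric!r}; choose from {METRICS}")


@dataclass
class BranchPartition:
    """Per-branch descendant totals: what every UniFrac variant sums over."""

    branch_lengths: np.ndarray        # (n_branches,)
    branch_counts: np.ndarray         # (n_branches, n_samples)
    sample_ids: list
    totals: np.ndarray                # (n_samples,) per-sample grand totals


def branch_partition(ds: BoundDataset) -> BranchPartition:
    """One post-order pass filling every branch's per-sample descendant total."""
    lt = LinearizedDataset(ds)
    return BranchPartition(
        branch_lengths=lt.branch_lengths,
        branch_counts=lt.branch_counts(ds.counts.astype(float)),
        sample_ids=list(ds.sample_ids),
        totals=ds.counts.sum(axis=0).astype(float),
    )


def _pair_indices(ds: BoundDataset, a: str, b: str) -> tuple[int, int]:
    ia = ds.table.sample_index(a)
    ib = ds.table.sample_index(b)
    for name, idx in ((a, ia), (b, ib)):
        if ds.counts[:, idx].sum() == 0:
            raise UniFracError(f"sample {name!r} has zero total count")
    return ia, ib


def unweighted_unifrac(ds: BoundDataset, a: str, b: str) -> float:
    """Fraction of covered branch length unique to one of the two samples."""
    ia, ib = _pair_indices(ds, a, b)
    return float(LinearizedDataset(ds).unweighted(ds.counts, ia, ib))


def weighted_unifrac(ds: BoundDataset, a: str, b: str,
                     normalized: bool = False) -> float:
    """Abundance-weighted UniFrac; ``normalized=True`` rescales into [0, 1]."""
    ia, ib = _pair_indices(ds, a, b)
    return float(LinearizedDataset(ds).weighted(ds.counts, ia, ib,
                                                normalized=normalized))


def pairwise_matrix(ds: BoundDataset, metric: str = "unweighted") -> pd.DataFrame:
    """Symmetric zero-diagonal distance matrix over all samples."""
    if metric not in METRICS:
        raise UniFracError(f"unknown metric {metric!r}; choose from {METRICS}")
    samples = ds.sample_ids
    if len(samples) < 2:
        raise UniFracError("need at least two samples")
    lt = LinearizedDataset(ds)
    out = np.zeros((len(samples), len(samples)))
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            try:
                _pair_indices(ds, samples[i], samples[j])
                out[i, j] = out[j, i] = float(
                    lt.evaluate(ds.counts, i, j, metric))
            except UniFracError as exc:
                raise UniFracError(
                    f"pair ({samples[i]!r}, {samples[j]!r}): {exc}") from exc
    return pd.DataFrame(out, index=samples, columns=samples)
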