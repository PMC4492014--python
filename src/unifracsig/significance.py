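"""Monte Carlo UniFrac significance tests with selectable null models.

All label-permutation schemes keep the tree topology and branch lengths fixed
and move counts between tips; they differ in what the permutable unit is:

``SEQUENCE_LEVEL``
    Expand the dataset so every sequence occurrence is a count-1 tip, then
    permute the per-tip count vectors uniformly across all expanded tips.
    Clonal sequences are reassigned independently of each other.
``OTU_LEVEL``
    Collapse the dataset so every OTU is a single counted tip, then permute
    per-tip count vectors uniformly across tips.  Clonal sequences travel
    together.
``WITHIN_TIP_SWAP``
    For each tip independently, with probability 1/2 exchange the two
    samples' counts.  Included because "swapping sample labels and their
    counts on a tip-by-tip basis" is readable as either a global permutation
    or per-tip swaps; both are provided.

Monte Carlo p-values use the pseudo-count convention
``p = (1 + #{null >= observed}) / (1 + n_permutations)`` with ties counted
as extreme; :func:`exact_test` enumerates the full permutation distribution
and reports the exact tail fraction ``#{null >= observed} / total``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product

import numpy as np

from .io import BoundDataset
from .transform import collapse_replicates, expand_replicates
from .unifrac import METRICS, LinearizedDataset, UniFracError, _pair_indices


class SignificanceError(ValueError):
    pass


class PermutationScheme(str, Enum):
    SEQUENCE_LEVEL = "sequence"
    OTU_LEVEL = "otu"
    WITHIN_TIP_SWAP = "within-tip"

    @classmethod
    def coerce(cls, value) -> "PermutationScheme":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise SignificanceError(
                f"unknown scheme {value!r}; choose from "
                f"{[s.value for s in cls]}") from None


@dataclass
class SignificanceResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    scheme: PermutationScheme
    metric: str
    n_permutations: int
    seed: int | None
    method: str = "monte_carlo"
    samples: tuple = field(default=())


def _scheme_encoding(ds: BoundDataset, scheme: PermutationScheme) -> BoundDataset:
    if scheme is PermutationScheme.SEQUENCE_LEVEL:
        return expand_replicates(ds)
    if scheme is PermutationScheme.OTU_LEVEL:
        return collapse_replicates(ds)
    return ds


def permute(ds: BoundDataset, scheme: PermutationScheme | str,
            rng: np.random.Generator) -> BoundDataset:
    """One randomized dataset: same topology and branch lengths, moved counts."""
    scheme = PermutationScheme.coerce(scheme)
    ds_s = _scheme_encoding(ds, scheme)
    counts = np.array(ds_s.counts)
    if scheme is PermutationScheme.WITHIN_TIP_SWAP:
        if counts.shape[1] != 2:
            raise SignificanceError(
                "WITHIN_TIP_SWAP is defined for exactly two samples")
        swap = rng.random(counts.shape[0]) < 0.5
        counts[swap] = counts[swap][:, ::-1]
    else:
        counts = counts[rng.permutation(counts.shape[0])]
    return ds_s.with_counts(counts)


def _permuted_counts(counts: np.ndarray, scheme: PermutationScheme,
                     seed: int, n: int) -> np.ndarray:
    """Stack of ``n`` permuted count matrices, one independent stream each."""
    children = np.random.SeedSequence(seed).spawn(n)
    out = np.empty((n,) + counts.shape, dtype=counts.dtype)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if scheme is PermutationScheme.WITHIN_TIP_SWAP:
            permuted = np.array(counts)
            swap = rng.random(counts.shape[0]) < 0.5
            permuted[swap] = permuted[swap][:, ::-1]
            out[i] = permuted
        else:
            out[i] = counts[rng.permutation(counts.shape[0])]
    return out


def monte_carlo_test(ds: BoundDataset, a: str, b: str,
                     metric: str = "weighted",
                     scheme: PermutationScheme | str = PermutationScheme.OTU_LEVEL,
                     n_permutations: int = 999,
                     seed: int = 0) -> SignificanceResult:
    """Permutation p-value for the distance between samples ``a`` and ``b``.

    The observed statistic is computed on the dataset as given (by the
    encoding-invariance of UniFrac it equals its value under either tree
    format); null statistics are computed on the scheme's own encoding.
    Deterministic: permutation ``i`` draws from a stream derived from
    ``(seed, i)``, so results are reproducible and order-independent.
    """
    if metric not in METRICS:
        raise UniFracError(f"unknown metric {metric!r}; choose from {METRICS}")
    if n_permutations < 1:
        raise SignificanceError("n_permutations must be >= 1")
    scheme = PermutationScheme.coerce(scheme)
    ia, ib = _pair_indices(ds, a, b)
    observed = float(LinearizedDataset(ds).evaluate(ds.counts, ia, ib, metric))
    ds_s = _scheme_encoding(ds, scheme)
    if scheme is PermutationScheme.WITHIN_TIP_SWAP and ds_s.counts.shape[1] != 2:
        raise SignificanceError(
            "WITHIN_TIP_SWAP is defined for exactly two samples")
    lt = LinearizedDataset(ds_s)
    stacks = _permuted_counts(ds_s.counts, scheme, seed, n_permutations)
    null = np.asarray(lt.evaluate(stacks, ia, ib, metric, warn_on_empty=False),
                      dtype=float)
    k = int(np.sum(null >= observed))
    return SignificanceResult(
        observed=observed, null_values=null,
        p_value=(1 + k) / (1 + n_permutations),
        scheme=scheme, metric=metric, n_permutations=n_permutations,
        seed=seed, method="monte_carlo", samples=(a, b))


def _distinct_permutations(rows: list[tuple]) -> "iterator":
    from sympy.utilities.iterables import multiset_permutations
    return multiset_permutations(sorted(rows))


def exact_test(ds: BoundDataset, a: str, b: str,
               metric: str = "weighted",
               scheme: PermutationScheme | str = PermutationScheme.OTU_LEVEL,
               max_units: int = 10) -> SignificanceResult:
    """Enumerate the full null distribution (oracle for the Monte Carlo test).

    Every distinct assignment of the multiset of count vectors to tips is
    enumerated exactly once; distinct assignments are equiprobable, so the
    exact p-value is the plain tail fraction ``#{null >= observed} / total``
    (no pseudo-count).  Refuses instances with more than ``max_units``
    permutable units.
    """
    if metric not in METRICS:
        raise UniFracError(f"unknown metric {metric!r}; choose from {METRICS}")
    scheme = PermutationScheme.coerce(scheme)
    ia, ib = _pair_indices(ds, a, b)
    observed = float(LinearizedDataset(ds).evaluate(ds.counts, ia, ib, metric))
    ds_s = _scheme_encoding(ds, scheme)
    n_units = ds_s.counts.shape[0]
    if n_units > max_units:
        raise SignificanceError(
            f"{n_units} permutable units exceed the enumeration limit "
            f"({max_units}); use monte_carlo_test")
    lt = LinearizedDataset(ds_s)
    if scheme is PermutationScheme.WITHIN_TIP_SWAP:
        if ds_s.counts.shape[1] != 2:
            raise SignificanceError(
                "WITHIN_TIP_SWAP is defined for exactly two samples")
        stacks = np.empty((2 ** n_units,) + ds_s.counts.shape, dtype=np.int64)
        for i, mask in enumerate(product((False, True), repeat=n_units)):
            permuted = np.array(ds_s.counts)
            mask = np.array(mask)
            permuted[mask] = permuted[mask][:, ::-1]
            stacks[i] = permuted
    else:
        rows = [tuple(r) for r in ds_s.counts]
        stacks = np.array(list(_distinct_permutations(rows)), dtype=np.int64)
    null = np.asarray(lt.evaluate(stacks, ia, ib, metric, warn_on_empty=False),
                      dtype=float)
    k = int(np.sum(null >= observed))
    return SignificanceResult(
        observed=observed, null_values=null, p_value=k / len(null),
        scheme=scheme, metric=metric, n_permutations=len(null),
        seed=None, method="exact", samples=(a, b))
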