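"""Parsimony-based community test: Fitch change counts on randomized topologies.

Instead of permuting sample labels on a fixed tree, this test keeps each
tip's sample label fixed and randomizes the tree topology itself.  The
statistic is the minimum number of sample-label state changes over the tree
(small parsimony); few changes mean the samples segregate into clades, so the
lower tail is significant: ``p = (1 + #{null <= observed}) / (1 + n)``.

Multifurcations use the generalized (Hartigan) rule: at an internal node with
children state sets S_1..S_k, let m be the largest number of children whose
sets share a state; the node's set is the states attaining m and the change
count increases by k - m.  For bifurcations this reduces to classic Fitch
(intersection if non-empty, else union plus one change).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import BoundDataset
from .transform import expand_replicates, prune_empty_tips
from .tree import TreeNode


class PTestError(ValueError):
    pass


@dataclass
class PTestResult:
    observed_changes: int
    null_changes: np.ndarray
    p_value: float
    n_randomizations: int
    seed: int


def fitch_changes(tree: TreeNode, tip_labels: Mapping[str, str]) -> int:
    """Minimum number of label state changes over the tree; lengths ignored."""
    changes = 0
    states: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            try:
                states[id(node)] = frozenset([tip_labels[node.name]])
            except KeyError:
                raise PTestError(f"unlabeled tip: {node.name!r}") from None
        else:
            tally: Counter = Counter()
            for child in node.children:
                tally.update(states.pop(id(child)))
            m = max(tally.values())
            states[id(node)] = frozenset(s for s, c in tally.items() if c == m)
            changes += len(node.children) - m
    return changes


def random_topology(tip_names: Sequence[str],
                    rng: np.random.Generator) -> TreeNode:
    """Uniform sequential pair-joining: rooted, bifurcating, unit lengths.

    Each step joins a uniformly chosen pair of the remaining lineages under a
    new parent, until one lineage (the root) remains.  Labels stay attached to
    their tips; all branch lengths are 1 (parsimony ignores them anyway).
    """
    if len(tip_names) < 2:
        raise PTestError("need at least 2 tips to build a topology")
    lineages = [TreeNode(name, 1.0) for name in tip_names]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        joined = TreeNode(None, 1.0, [lineages[i], lineages[j]])
        lineages[i] = joined
        lineages.pop(j)
    root = lineages[0]
    root.length = 0.0
    return root


def p_test(ds: BoundDataset, n_randomizations: int = 999, seed: int = 0,
           randomizer: Callable[[Sequence[str], np.random.Generator], TreeNode]
           = random_topology) -> PTestResult:
    """P test over all samples of a dataset.

    Counted tips are expanded first so abundance enters through tip
    multiplicity, and zero-count tips are pruned; every remaining tip then
    belongs to exactly one sample.  The null randomizes topology over the same
    labeled tips (``randomizer`` is pluggable; the default joins uniform
    random pairs sequentially).
    """
    if n_randomizations < 1:
        raise PTestError("n_randomizations must be >= 1")
    ds_x = prune_empty_tips(expand_replicates(ds))
    sample_arr = np.asarray(ds_x.sample_ids)
    labels: dict[str, str] = {}
    for tip, vec in zip(ds_x.tip_ids, ds_x.counts):
        (nz,) = np.nonzero(vec)
        labels[tip] = str(sample_arr[nz[0]])
    if len(set(labels.values())) < 2:
        raise PTestError("P test needs at least two samples with counts")
    observed = fitch_changes(ds_x.tree, labels)
    tip_names = list(labels)
    null = np.empty(n_randomizations, dtype=np.int64)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_randomizations)):
        topo = randomizer(tip_names, np.random.default_rng(child))
        null[i] = fitch_changes(topo, labels)
    k = int(np.sum(null <= observed))
    return PTestResult(
        observed_changes=observed, null_changes=null,
        p_value=(1 + k) / (1 + n_randomizations),
        n_randomizations=n_randomizations, seed=seed)
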