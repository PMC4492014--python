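"""Conversions between the two tree encodings of counted sequences.

The *collapsed* encoding keeps one tip per OTU with a per-sample count
vector.  The *expanded* encoding gives every sequence occurrence its own tip
with a count of 1, hanging from the OTU's position by a zero-length branch.
Both encodings yield identical UniFrac values but define different permutable
units for significance testing, which is why both are first-class here.
"""

from __future__ import annotations

import numpy as np

from .io import AbundanceTable, BoundDataset, bind
from .tree import TreeNode


class TransformError(ValueError):
    pass


def _rebuild(tree: TreeNode, counts_by_tip: dict[str, np.ndarray],
             sample_ids: list[str]) -> BoundDataset:
    tip_order = tree.tip_names()
    n = len(sample_ids)
    counts = np.zeros((len(tip_order), n), dtype=np.int64)
    for i, tip in enumerate(tip_order):
        if tip in counts_by_tip:
            counts[i] = counts_by_tip[tip]
    return bind(tree, AbundanceTable(tip_order, sample_ids, counts))


def expand_replicates(ds: BoundDataset) -> BoundDataset:
    """Give every sequence occurrence its own count-1 tip.

    A tip with total count c >= 2 becomes an internal node (same name, same
    branch length) with c children on zero-length branches, one child per
    occurrence, named ``<orig>__<sample>__<k>`` for k = 1..count within each
    sample.  Tips with total count 0 or 1 are left untouched.
    """
    tree = ds.tree.copy()
    sample_ids = ds.sample_ids
    counts_by_tip: dict[str, np.ndarray] = {}
    vectors = dict(zip(ds.tip_ids, ds.counts))
    for tip in list(tree.tips()):
        vec = vectors[tip.name]
        if vec.sum() <= 1:
            counts_by_tip[tip.name] = vec
            continue
        for j, sample in enumerate(sample_ids):
            for k in range(1, int(vec[j]) + 1):
                name = f"{tip.name}__{sample}__{k}"
                tip.add_child(TreeNode(name, 0.0))
                unit = np.zeros(len(sample_ids), dtype=np.int64)
                unit[j] = 1
                counts_by_tip[name] = unit
    return _rebuild(tree, counts_by_tip, sample_ids)


def _zero_reachable_tips(node: TreeNode) -> list[TreeNode]:
    """Tips reachable from ``node`` following only zero-length branches."""
    out: list[TreeNode] = []
    for child in node.children:
        if child.length == 0:
            if child.is_tip:
                out.append(child)
            else:
                out.extend(_zero_reachable_tips(child))
    return out


def _merged_name(tips: list[TreeNode], taken: set[str]) -> str:
    if len(tips) == 1:
        name = tips[0].name
    else:
        bases = {t.name.split("__")[0] for t in tips}
        name = bases.pop() if len(bases) == 1 else tips[0].name
    while name in taken:
        name += "__merged"
    return name


def collapse_replicates(ds: BoundDataset) -> BoundDataset:
    """Merge every maximal set of tips at pairwise path distance zero.

    Each maximal group of tips connected to a common ancestor exclusively
    through zero-length branches becomes one tip carrying the element-wise sum
    of the group's count vectors.  When the group is the ancestor's entire
    subtree the merged tip replaces the ancestor (inheriting its branch
    length); otherwise it attaches to the ancestor by a zero-length branch.
    Inverts :func:`expand_replicates` whenever original tip branches have
    positive length.
    """
    tree = ds.tree.copy()
    counts: dict[str, np.ndarray] = dict(zip(ds.tip_ids, ds.counts))
    # anchors: nodes at which a zero-length region is maximal
    anchors = [n for n in tree.preorder()
               if not n.is_tip and (n.is_root or n.length > 0)]
    for anchor in anchors:
        if anchor.parent is None and anchor is not tree:
            continue  # detached by an earlier full-subtree replacement
        zero_tips = _zero_reachable_tips(anchor)
        if not zero_tips:
            continue
        subtree_tips = [t for t in anchor.preorder() if t.is_tip]
        whole_subtree = len(zero_tips) == len(subtree_tips)
        if not whole_subtree and len(zero_tips) < 2:
            continue
        merged_vec = np.sum([counts.pop(t.name) for t in zero_tips], axis=0)
        remaining = set(counts)
        name = _merged_name(zero_tips, remaining)
        counts[name] = merged_vec
        if whole_subtree:
            anchor.children = []
            anchor.name = name
        else:
            zero_internals = [n for n in anchor.preorder()
                              if not n.is_tip and n is not anchor
                              and n.length == 0]
            for t in zero_tips:
                t.parent.remove_child(t)
            for node in reversed(zero_internals):  # bottom-up cleanup
                if not node.children:
                    node.parent.remove_child(node)
                elif len(node.children) == 1:
                    child = node.children[0]
                    child.length += node.length
                    parent = node.parent
                    idx = parent.children.index(node)
                    node.remove_child(child)
                    parent.children[idx] = child
                    child.parent = parent
            anchor.add_child(TreeNode(name, 0.0))
    return _rebuild(tree, counts, ds.sample_ids)


def prune_empty_tips(ds: BoundDataset) -> BoundDataset:
    """Drop tips with all-zero counts; splice resulting unary internal nodes.

    Splicing sums branch lengths (``child.length += node.length``) so every
    surviving tip keeps its path length to the root; a root left with a single
    child keeps that child (its branch may be shared by both samples and must
    survive), so both UniFrac metrics are unchanged by pruning.
    """
    tree = ds.tree.copy()
    counts = dict(zip(ds.tip_ids, ds.counts))
    doomed = [t for t in tree.tips() if counts[t.name].sum() == 0]
    if len(doomed) == len(ds.tip_ids):
        raise TransformError("pruning would remove every tip")
    internals = [n for n in tree.postorder() if not n.is_tip]
    for tip in doomed:
        del counts[tip.name]
        tip.parent.remove_child(tip)
    for node in internals:
        if node.is_root or node.parent is None:
            continue
        if not node.children:
            node.parent.remove_child(node)
        elif len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            parent = node.parent
            idx = parent.children.index(node)
            node.remove_child(child)
            parent.children[idx] = child
            child.parent = parent
    return _rebuild(tree, counts, ds.sample_ids)
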