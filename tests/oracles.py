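"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive every quantity from first principles (explicit
descendant-tip enumeration, exhaustive minimization) and share no code with
the package's accumulation kernels.
"""

from __future__ import annotations

from itertools import product

def _descendant_tips(node):
    return [t.name for t in node.preorder() if t.is_tip]


def brute_force_unifrac(ds, a, b, metric):
    """UniFrac by explicit per-branch descendant tip-set enumeration."""
    ia = ds.sample_ids.index(a)
    ib = ds.sample_ids.index(b)
    vec = dict(zip(ds.tip_ids, ds.counts))
    na_tot = sum(int(v[ia]) for v in vec.values())
    nb_tot = sum(int(v[ib]) for v in vec.values())
    unique = shared = w = 0.0
    for node in ds.tree.preorder():
        if node.is_root:
            continue
        tips = _descendant_tips(node)
        na = sum(int(vec[t][ia]) for t in tips)
        nb = sum(int(vec[t][ib]) for t in tips)
        if na > 0 or nb > 0:
            shared += node.length
            if (na > 0) != (nb > 0):
                unique += node.length
        w += node.length * abs(na / na_tot - nb / nb_tot)
    if metric == "unweighted":
        return unique / shared if shared > 0 else 0.0
    if metric == "weighted":
        return w
    # weighted-normalized: root-to-tip depths by explicit path walking
    d = 0.0
    for tip in ds.tree.tips():
        depth, node = 0.0, tip
        while node.parent is not None:
            depth += node.length
            node = node.parent
        v = vec[tip.name]
        d += depth * (int(v[ia]) / na_tot + int(v[ib]) / nb_tot)
    return w / d


def brute_force_fitch(tree, tip_labels):
    """Minimum label changes by exhaustive search over ancestral labelings."""
    internals = [n for n in tree.postorder() if not n.is_tip]
    states = sorted(set(tip_labels.values()))
    best = None
    for assignment in product(states, repeat=len(internals)):
        label = {id(n): s for n, s in zip(internals, assignment)}
        for tip in tree.tips():
            label[id(tip)] = tip_labels[tip.name]
        changes = sum(1 for n in tree.preorder() if n.parent is not None
                      and label[id(n)] != label[id(n.parent)])
        best = changes if best is None else min(best, changes)
    return best


def pairwise_zero_distance_tips(tree):
    """All unordered tip pairs at path distance zero (brute-force scan)."""
    tips = list(tree.tips())
    depths = tree.depths()
    pairs = set()
    for i, t1 in enumerate(tips):
        for t2 in tips[i + 1:]:
            # distance via lowest common ancestor
            anc1 = {id(t1): t1}
            node = t1
            while node.parent is not None:
                node = node.parent
                anc1[id(node)] = node
            node = t2
            while id(node) not in anc1:
                node = node.parent
            lca = node
            dist = depths[t1] + depths[t2] - 2 * depths[lca]
            if dist == 0:
                pairs.add(frozenset((t1.name, t2.name)))
    return pairs
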