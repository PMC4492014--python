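"""Synthetic trees and two-sample datasets, plus the packaged experiments.

Datasets are built in the collapsed (one tip per OTU) encoding: a random
rooted bifurcating tree with exponential branch lengths, a Dirichlet-drawn
composition over its tips, and multinomial counts per sample.  Deep
multinomials over few OTUs put counts > 1 on tips — exactly the regime where
the sequence-level and OTU-level permutation nulls diverge.

Randomness discipline: :func:`simulate_dataset` splits its generator into
independent child streams (tree, composition, clade choice, counts), so a
clade-shift effect with fold_change 1 is byte-identical to effect "none"
under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, BoundDataset, bind
from .significance import PermutationScheme, monte_carlo_test
from .transform import expand_replicates
from .tree import TreeNode
from .unifrac import unweighted_unifrac, weighted_unifrac

SAMPLE_IDS = ("S1", "S2")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """Parameters of one synthetic two-sample dataset family."""

    n_otus: int = 16
    depth: int = 100               # sequences per sample
    dirichlet_alpha: float = 1.0   # symmetric Dirichlet concentration
    branch_rate: float = 1.0       # exponential rate for branch lengths
    effect: str = "none"           # "none" | "clade_shift"
    clade_fraction: float = 0.3    # tip fraction covered by the shifted clade
    fold_change: float = 1.0

    def __post_init__(self):
        if self.n_otus < 1:
            raise ScenarioError("n_otus must be >= 1")
        if self.depth < 1:
            raise ScenarioError("depth must be >= 1")
        if self.dirichlet_alpha <= 0 or self.branch_rate <= 0:
            raise ScenarioError("dirichlet_alpha and branch_rate must be > 0")
        if self.effect not in ("none", "clade_shift"):
            raise ScenarioError(f"unknown effect {self.effect!r}")
        if self.effect == "clade_shift":
            if not 0 < self.clade_fraction < 1:
                raise ScenarioError("clade_fraction must lie in (0, 1)")
            if self.fold_change <= 0:
                raise ScenarioError("fold_change must be > 0")

    @property
    def replication(self) -> float:
        """Mean per-OTU count per sample; > 1 means replicated sequences."""
        return self.depth / self.n_otus

    @classmethod
    def from_config(cls, text: str) -> "Scenario":
        """Parse a plain ``key=value`` config (one per line, '#' comments)."""
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ScenarioError(f"config line {lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ScenarioError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)


def random_tree(n_tips: int, rng: np.random.Generator,
                branch_rate: float = 1.0, prefix: str = "OTU") -> TreeNode:
    """Random rooted bifurcating tree by sequential uniform pair-joining,
    with i.i.d. exponential branch lengths."""
    if n_tips == 1:
        return TreeNode(f"{prefix}1", 0.0)
    lengths = iter(rng.exponential(1.0 / branch_rate, size=2 * n_tips - 2))
    lineages = [TreeNode(f"{prefix}{i + 1}", next(lengths))
                for i in range(n_tips)]
    while len(lineages) > 1:
        i, j = sorted(int(x) for x in
                      rng.choice(len(lineages), size=2, replace=False))
        length = next(lengths) if len(lineages) > 2 else 0.0
        lineages[i] = TreeNode(None, length, [lineages[i], lineages[j]])
        lineages.pop(j)
    return lineages[0]


def _shifted_composition(tree: TreeNode, p: np.ndarray, tip_ids: list[str],
                         sc: Scenario, rng: np.random.Generator) -> np.ndarray:
    internal = [n for n in tree.preorder() if not n.is_tip]
    if not internal:
        return p
    target = sc.clade_fraction * len(tip_ids)
    sizes = {id(n): sum(1 for t in n.preorder() if t.is_tip) for n in internal}
    best = min(abs(sizes[id(n)] - target) for n in internal)
    candidates = [n for n in internal if abs(sizes[id(n)] - target) == best]
    clade = candidates[int(rng.integers(len(candidates)))]
    member = {t.name for t in clade.tips()}
    mask = np.array([t in member for t in tip_ids])
    shifted = np.where(mask, p * sc.fold_change, p)
    return shifted / shifted.sum()


def simulate_dataset(sc: Scenario, rng: np.random.Generator) -> BoundDataset:
    """One synthetic dataset; deterministic given the generator's state."""
    r_tree, r_comp, r_clade, r_counts = rng.spawn(4)
    tree = random_tree(sc.n_otus, r_tree, sc.branch_rate)
    tip_ids = tree.tip_names()
    if sc.n_otus == 1:
        counts = np.full((1, 2), sc.depth, dtype=np.int64)
    else:
        p = r_comp.dirichlet(np.full(sc.n_otus, sc.dirichlet_alpha))
        p2 = p
        if sc.effect == "clade_shift":
            p2 = _shifted_composition(tree, p, tip_ids, sc, r_clade)
        counts = np.column_stack([r_counts.multinomial(sc.depth, p),
                                  r_counts.multinomial(sc.depth, p2)])
    table = AbundanceTable(tip_ids, list(SAMPLE_IDS), counts)
    return bind(tree, table)


def discrepancy_experiment(sc: Scenario, n_datasets: int = 20,
                           n_permutations: int = 999, seed: int = 0,
                           metric: str = "weighted") -> pd.DataFrame:
    """Quantify how the choice of permutable unit changes the null.

    For each simulated dataset: the observed unweighted and weighted UniFrac
    under both encodings (asserted equal to 1e-12), the Monte Carlo p-value
    under the sequence-level and OTU-level schemes, and the two-sample
    Kolmogorov-Smirnov statistic between the two schemes' null samples.
    """
    rows = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_datasets)):
        ds = simulate_dataset(sc, np.random.default_rng(child))
        ds_x = expand_replicates(ds)
        a, b = SAMPLE_IDS
        u_c = unweighted_unifrac(ds, a, b)
        u_x = unweighted_unifrac(ds_x, a, b)
        w_c = weighted_unifrac(ds, a, b)
        w_x = weighted_unifrac(ds_x, a, b)
        assert abs(u_c - u_x) < 1e-12 and abs(w_c - w_x) < 1e-12, \
            "encoding changed the observed UniFrac value"
        res_seq = monte_carlo_test(ds, a, b, metric=metric,
                                   scheme=PermutationScheme.SEQUENCE_LEVEL,
                                   n_permutations=n_permutations, seed=seed + i)
        res_otu = monte_carlo_test(ds, a, b, metric=metric,
                                   scheme=PermutationScheme.OTU_LEVEL,
                                   n_permutations=n_permutations, seed=seed + i)
        ks = stats.ks_2samp(res_seq.null_values, res_otu.null_values)
        rows.append({
            "dataset": i,
            "unweighted_collapsed": u_c, "unweighted_expanded": u_x,
            "weighted_collapsed": w_c, "weighted_expanded": w_x,
            "p_sequence": res_seq.p_value, "p_otu": res_otu.p_value,
            "p_diff": res_seq.p_value - res_otu.p_value,
            "ks_statistic": float(ks.statistic),
        })
    return pd.DataFrame(rows)


def type1_experiment(sc: Scenario, n_datasets: int = 1000,
                     alpha: float = 0.05,
                     scheme: PermutationScheme | str = PermutationScheme.OTU_LEVEL,
                     n_permutations: int = 99, seed: int = 0,
                     metric: str = "weighted") -> dict:
    """Rejection rate at level ``alpha`` on data simulated under the null."""
    if sc.effect != "none":
        raise ScenarioError("type-I experiment requires effect='none'")
    scheme = PermutationScheme.coerce(scheme)
    p_values = np.empty(n_datasets)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_datasets)):
        ds = simulate_dataset(sc, np.random.default_rng(child))
        res = monte_carlo_test(ds, *SAMPLE_IDS, metric=metric, scheme=scheme,
                               n_permutations=n_permutations, seed=seed + i)
        p_values[i] = res.p_value
    return {
        "scheme": scheme.value, "metric": metric, "alpha": alpha,
        "n_datasets": n_datasets, "n_permutations": n_permutations,
        "seed": seed,
        "rejection_rate": float(np.mean(p_values <= alpha)),
        "p_values": p_values,
    }


def replicated_fixture() -> BoundDataset:
    """Small collapsed dataset with replicated sequences (<= 8 expanded tips).

    The exact sequence-level and OTU-level nulls on this fixture have
    different supports while the observed statistic is encoding-invariant.
    """
    from .io import AbundanceTable
    from .tree import parse_newick
    tree = parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
    table = AbundanceTable(
        ["A", "B", "C", "D"], list(SAMPLE_IDS),
        [[3, 0], [0, 1], [0, 2], [1, 0]])
    return bind(tree, table)
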