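# unifracsig

UniFrac phylogenetic beta-diversity distances (unweighted, weighted raw and
normalized) together with Monte Carlo significance tests whose null model is
an **explicit, selectable choice** — because the choice of permutable unit
changes the null distribution (and hence the p-value) even though it never
changes the observed UniFrac value.

A counted community can be encoded on a tree in two equivalent-looking ways:

- **collapsed** — one tip per OTU carrying a per-sample count vector;
- **expanded** — one tip per *sequence occurrence* (a tip counted 4 times
  becomes 4 count-1 tips on zero-length branches under a shared parent).

Both encodings give identical UniFrac values (verified to `1e-12` in the test
suite). But permuting labels tip-by-tip on the two encodings builds *different*
null distributions: OTU-level permutation keeps clonal sequences together,
sequence-level permutation reassigns them independently. This package makes
the distinction concrete, measurable, and reproducible.

## What's inside

| module | contents |
|---|---|
| `unifracsig.tree` | `TreeNode`, Newick `parse_newick` / `write_newick` (quoted labels, offsets in parse errors, full-precision round trip) |
| `unifracsig.io` | `AbundanceTable` (TSV), `bind` → `BoundDataset` (tree tips missing from the table get zero counts) |
| `unifracsig.transform` | `expand_replicates`, `collapse_replicates`, `prune_empty_tips` |
| `unifracsig.unifrac` | `unweighted_unifrac`, `weighted_unifrac(normalized=...)`, `branch_partition`, `pairwise_matrix`, vectorized `LinearizedDataset` kernel |
| `unifracsig.significance` | `PermutationScheme` (`sequence`, `otu`, `within-tip`), `permute`, `monte_carlo_test`, `exact_test` (full enumeration oracle) |
| `unifracsig.ptest` | `fitch_changes` (Hartigan rule on multifurcations), `random_topology`, `p_test` (labels fixed, topology randomized) |
| `unifracsig.synthetic` | `Scenario`, `simulate_dataset`, `discrepancy_experiment`, `type1_experiment`, `replicated_fixture` |

p-value conventions: Monte Carlo tests report `(1 + k) / (1 + n)` with ties
counted as extreme; `exact_test` enumerates every distinct permutation and
reports the plain tail fraction. All stochastic entry points take a single
integer seed and are byte-reproducible (each permutation draws from a stream
derived from `(seed, index)`).

## CLI

Inputs are a rooted Newick tree and a TSV count table with header
`#TIP_ID<TAB>sample1<TAB>...` (non-negative integer counts, tip IDs matching
tree tip names). An unrooted (trifurcating) Newick is accepted with its top
node treated as the root — note that rooting affects both metrics.

```sh
# distance matrix
unifracsig dist --metric weighted --tree t.nwk --table t.tsv --out matrix.tsv

# Monte Carlo significance test with an explicit null model
unifracsig test --metric weighted --scheme otu --n 999 --seed 42 \
    --tree t.nwk --table t.tsv --null-out null_values.txt

# P test (parsimony statistic, randomized topology)
unifracsig ptest --tree t.nwk --table t.tsv --n 999 --seed 7

# re-encode between the two tree formats
unifracsig expand   --tree t.nwk --table t.tsv --out-tree x.nwk --out-table x.tsv
unifracsig collapse --tree x.nwk --table x.tsv --out-tree c.nwk --out-table c.tsv

# synthetic data and the packaged experiments
unifracsig simulate --n-otus 16 --depth 100 --seed 1 --out-prefix sim
unifracsig experiment discrepancy --n-otus 8 --depth 80 --n-datasets 20 \
    --n-permutations 999 --seed 1 --out report.tsv
unifracsig experiment type1 --scheme otu --n-datasets 1000 --seed 1
```

Scenario parameters can also come from a plain `key=value` file via
`--config` (keys: `n_otus`, `depth`, `dirichlet_alpha`, `branch_rate`,
`effect`, `clade_fraction`, `fold_change`).

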