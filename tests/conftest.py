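import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from unifracsig import AbundanceTable, Scenario, bind, parse_newick, \
    simulate_dataset


def make_dataset(newick, counts, sample_ids=("S1", "S2")):
    """Dataset from a Newick string and a {tip: (c1, c2, ...)} mapping."""
    tree = parse_newick(newick)
    tips = list(counts)
    table = AbundanceTable(tips, list(sample_ids),
                           np.array([counts[t] for t in tips]))
    return bind(tree, table)


def random_dataset(rng, n_otus=None, depth=None, **kwargs):
    """Random small collapsed dataset with positive branch lengths and
    both sample totals positive."""
    n_otus = n_otus or int(rng.integers(2, 13))
    depth = depth or int(rng.integers(5, 41))
    sc = Scenario(n_otus=n_otus, depth=depth, **kwargs)
    return simulate_dataset(sc, rng)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
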