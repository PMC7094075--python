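import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from paramicro import FeatureTable
from paramicro.synthetic import _random_subtree


@pytest.fixture
def four_leaf_tree():
    """((A:1,B:1):1,(C:1,D:1):1) -- two cherries of unit branches."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1):0;"))


@pytest.fixture
def toy_table():
    counts = np.array(
        [
            [5, 0, 1],
            [0, 3, 1],
            [2, 2, 1],
            [0, 0, 4],
        ]
    )
    return FeatureTable(("A", "B", "C", "D"), ("s1", "s2", "s3"), counts)


def random_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree with exponential branch lengths."""
    leaves = [
        TreeNode(name=f"T{i}", length=float(rng.exponential(0.5)))
        for i in range(n_tips)
    ]
    root = _random_subtree(leaves, rng, 0.5)
    root.length = None
    return root


def random_table(feature_ids, n_samples: int, rng: np.random.Generator) -> FeatureTable:
    counts = rng.integers(0, 50, size=(len(feature_ids), n_samples))
    # guarantee positive sample totals
    counts[rng.integers(0, len(feature_ids)), :] += 1
    return FeatureTable(
        tuple(feature_ids), tuple(f"s{j}" for j in range(n_samples)), counts
    )


@pytest.fixture
def taxonomy_frame():
    def make(feature_ids, phyla, orders):
        return pd.DataFrame(
            {
                "phylum": phyla,
                "class": ["c"] * len(feature_ids),
                "order": orders,
                "family": ["f"] * len(feature_ids),
                "genus": ["g"] * len(feature_ids),
            },
            index=list(feature_ids),
        )

    return make
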