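import io

import numpy as np
import pytest
from skbio import TreeNode

from assemblyscope.core_io import CountMatrix, GroupMap, Phylogeny, to_relative_abundance


@pytest.fixture
def toy_counts():
    """4 OTUs x 6 samples, two groups, hand-enterable numbers."""
    counts = np.array(
        [
            [5, 3, 4, 0, 0, 1],
            [2, 4, 3, 1, 0, 0],
            [0, 0, 1, 6, 5, 7],
            [1, 1, 0, 3, 4, 2],
        ]
    )
    return CountMatrix(["A", "B", "C", "D"], [f"s{i}" for i in range(6)], counts)


@pytest.fixture
def toy_rel(toy_counts):
    return to_relative_abundance(toy_counts)


@pytest.fixture
def toy_groups():
    return GroupMap({f"s{i}": ("G1" if i < 3 else "G2") for i in range(6)})


@pytest.fixture
def toy_tree():
    """((A:1,B:2):0.5,(C:1.5,D:0.5):1):0 over the toy OTUs."""
    return Phylogeny(TreeNode.read(io.StringIO("((A:1,B:2):0.5,(C:1.5,D:0.5):1);")))


@pytest.fixture
def star_tree():
    """Effectively a star: unit branches to every tip, zero-length interior."""
    return Phylogeny(TreeNode.read(io.StringIO("((A:1,B:1,C:1):0.0,D:1);")))
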