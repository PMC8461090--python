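import io

import numpy as np
import pytest
from skbio import TreeNode

from biofilm_assembly import CommunityTable


@pytest.fixture
def four_tip_tree() -> TreeNode:
    """Balanced 4-tip tree with unit branch lengths (total length 6)."""
    return TreeNode.read(io.StringIO("((t1:1,t2:1):1,(t3:1,t4:1):1);"))


@pytest.fixture
def small_table() -> CommunityTable:
    return CommunityTable(
        ["A", "B", "C"],
        ["t1", "t2"],
        np.array([[6, 2], [1, 3], [5, 5]]),
    )


@pytest.fixture
def random_table() -> CommunityTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(5, 12))
    counts[:, 0] += 1  # no zero-sum sample
    return CommunityTable(
        [f"S{i}" for i in range(5)], [f"t{j + 1}" for j in range(12)], counts
    )
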