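import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from bicpam import ExpressionMatrix
from bicpam.mapping import TransactionDatabase

#: the worked six-transaction itemset database over letters A..J
DEX_ITEMSETS = [
    {"B", "E", "G"},
    {"A", "B", "C", "E", "H", "J"},
    {"A", "B", "D", "H", "J"},
    {"D", "H", "J"},
    {"A", "H", "J"},
    {"A", "G"},
]


@pytest.fixture
def dex_db():
    return TransactionDatabase.from_itemsets(DEX_ITEMSETS)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    vals = rng.uniform(0.0, 10.0, size=(8, 5))
    return ExpressionMatrix(vals, [f"g{i}" for i in range(8)],
                            [f"c{j}" for j in range(5)])


def random_itemset_db(rng, max_transactions=12, max_items=8):
    nt = rng.integers(2, max_transactions + 1)
    ni = rng.integers(2, max_items + 1)
    sets = []
    for _ in range(nt):
        k = rng.integers(1, ni + 1)
        sets.append(set(rng.choice(ni, size=k, replace=False).tolist()))
    return sets
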