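import numpy as np
import pandas as pd
import pytest

from netgenstab import NodeTable, ValuedNetwork


def make_nodes(n: int, seed: int = 0, year: int = 2006) -> NodeTable:
    rng = np.random.default_rng(seed)
    return NodeTable(pd.DataFrame({
        "id": [f"n{i:03d}" for i in range(n)],
        "sex": rng.choice(["female", "male"], n),
        "x": rng.uniform(0, 20, n),
        "y": rng.uniform(0, 40, n),
        "year": year,
    }))


def random_network(n: int, seed: int = 0, density: float = 0.4,
                   wmax: int = 4) -> ValuedNetwork:
    """Small random valued network for oracle tests."""
    rng = np.random.default_rng(seed)
    w = rng.integers(1, wmax + 1, (n, n))
    w = np.triu(w, 1) * (rng.random((n, n)) < density)
    w = (w + w.T).astype(np.int64)
    return ValuedNetwork(make_nodes(n, seed + 1), w)


@pytest.fixture
def nodes3():
    """Three nodes: A, B female; C male (the worked statistic example)."""
    return NodeTable(pd.DataFrame({
        "id": ["A", "B", "C"],
        "sex": ["female", "female", "male"],
        "x": [0.0, 3.0, 0.0],
        "y": [0.0, 0.0, 4.0],
        "year": 2006,
    }))


@pytest.fixture
def net3(nodes3):
    """y_AB = 2, y_BC = 1, y_AC = 0."""
    w = np.array([[0, 2, 0], [2, 0, 1], [0, 1, 0]])
    return ValuedNetwork(nodes3, w)
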