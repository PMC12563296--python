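import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from dama.graph import Graph


@pytest.fixture
def triangle() -> Graph:
    return Graph(3, np.array([[0, 1], [1, 2], [0, 2]]))


@pytest.fixture
def path3() -> Graph:
    """Path 0–1–2."""
    return Graph(3, np.array([[0, 1], [1, 2]]))


@pytest.fixture
def star4() -> Graph:
    """Hub 0 with leaves 1, 2, 3."""
    return Graph(4, np.array([[0, 1], [0, 2], [0, 3]]))


@pytest.fixture
def two_triangles() -> Graph:
    g = Graph(6, np.array([[0, 1], [1, 2], [0, 2], [3, 4], [4, 5], [3, 5]]),
              labels=np.array([0, 0, 0, 1, 1, 1]))
    return g


def random_graph(n: int, p: float, seed: int, connected: bool = False) -> Graph:
    """Seeded Erdős–Rényi graph; optionally resample until connected."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    for k in range(200):
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(iu.size) < p
        g = Graph(n, np.column_stack([iu[keep], ju[keep]]))
        if not connected or nx.is_connected(g.to_networkx()):
            return g
    raise RuntimeError("could not draw a connected sample")
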