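import numpy as np
import pytest

from corrnets import CorrelationMatrix, FeatureTable, NetworkGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)


@pytest.fixture
def toy_table():
    """6 samples x 6 taxa count table, the canonical small input."""
    rng = np.random.default_rng(42)
    values = rng.integers(0, 50, size=(6, 6)).astype(float)
    return FeatureTable(
        tuple(f"S{i}" for i in range(1, 7)),
        tuple(f"B{j}" for j in range(1, 7)),
        values,
    )


def make_corr(feature_ids, entries):
    """Symmetric correlation matrix from {(i, j): r} index pairs."""
    p = len(feature_ids)
    m = np.eye(p)
    for (i, j), r in entries.items():
        m[i, j] = m[j, i] = r
    return CorrelationMatrix(tuple(feature_ids), m)


def make_graph(edges, threshold=0.8, mode="both"):
    """NetworkGraph from {(u, v): weight}; nodes are the edge endpoints."""
    edges = {tuple(sorted(e)): w for e, w in edges.items()}
    nodes = tuple(sorted({n for e in edges for n in e}))
    return NetworkGraph(nodes, edges, threshold, mode)


@pytest.fixture
def three_feature_matrix():
    """r(1,2)=0.9, r(1,3)=0.5, r(2,3)=-0.85 on features a, b, c."""
    return make_corr(["a", "b", "c"], {(0, 1): 0.9, (0, 2): 0.5, (1, 2): -0.85})
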