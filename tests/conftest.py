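import numpy as np
import pytest

from kglink.embed import Node2VecParams, embed_graph
from kglink.graph import KnowledgeGraph
from kglink.synthetic import generate_kg, rnakg_like_preset


def make_graph(n, edges, types=None, edge_types=None, ids=None):
    """Small typed graph from an edge list of dense-index pairs."""
    ids = ids if ids is not None else [f"n{i:03d}" for i in range(n)]
    types = types if types is not None else ["A"] * n
    edge_types = edge_types if edge_types is not None else ["e"] * len(edges)
    return KnowledgeGraph(ids, types, np.asarray(edges, dtype=np.int64).reshape(-1, 2),
                          edge_types)


def clique_pair(size=10):
    """Two disconnected cliques of ``size`` nodes each (indices split at size)."""
    edges = []
    for base in (0, size):
        for i in range(size):
            for j in range(i + 1, size):
                edges.append((base + i, base + j))
    return make_graph(2 * size, edges)


def cosine_matrix(vectors):
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    v = vectors / np.where(norms > 0, norms, 1.0)
    return v @ v.T


def clique_separation(vectors, size=10):
    """(mean intra-clique cosine, mean inter-clique cosine) for clique_pair."""
    s = cosine_matrix(vectors)
    n = 2 * size
    intra, inter = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (intra if (i < size) == (j < size) else inter).append(s[i, j])
    return float(np.mean(intra)), float(np.mean(inter))


@pytest.fixture(scope="session")
def small_preset():
    spec = rnakg_like_preset("small", seed=0)
    g, truth = generate_kg(spec)
    return spec, g, truth


@pytest.fixture(scope="session")
def preset_bfs_embedding(small_preset):
    """BFS-like node2vec 10-D embedding of the full small-preset graph.

    Walk/epoch counts are the package's evaluation-scale configuration
    (10 walks of length 50 per node, 3 epochs).
    """
    _, g, _ = small_preset
    params = Node2VecParams.bfs(dim=10, walks_per_node=10, walk_length=50,
                                epochs=3, seed=1)
    return embed_graph(g, params)
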