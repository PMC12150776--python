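import numpy as np
import pytest

from kglink.embed import (EmbeddingMatrix, LINEParams, Node2VecParams,
                          embed_graph, generate_walks, load_embedding,
                          project_2d, save_embedding, train_line,
                          train_skipgram, transition_distribution)

from conftest import clique_pair, clique_separation, make_graph


def _brute_force_transition(g, prev, curr, params):
    """Independent enumeration of the node2vec weight rule."""
    nbrs = [int(x) for x in g.neighbors(curr)]
    if prev is None:
        return {v: 1.0 / len(nbrs) for v in nbrs}
    w = {}
    for cand in nbrs:
        if cand == prev:
            w[cand] = params.return_weight
        elif g.has_edge(prev, cand):
            w[cand] = 1.0
        else:
            w[cand] = params.explore_weight
    total = sum(w.values())
    return {v: x / total for v, x in w.items()}


PRESETS = [Node2VecParams.bfs(), Node2VecParams.dfs(), Node2VecParams.balanced()]


def test_walk_presets_reproduce_named_settings():
    assert (PRESETS[0].return_weight, PRESETS[0].explore_weight) == (5.0, 0.2)
    assert (PRESETS[1].return_weight, PRESETS[1].explore_weight) == (0.2, 5.0)
    assert (PRESETS[2].return_weight, PRESETS[2].explore_weight) == (1.0, 1.0)


def test_transition_path_balanced_is_uniform():
    g = make_graph(3, [(0, 1), (1, 2)])
    p = transition_distribution(g, 0, 1, Node2VecParams.balanced())
    assert p == pytest.approx({0: 0.5, 2: 0.5})


def test_transition_path_bfs_prefers_return():
    g = make_graph(3, [(0, 1), (1, 2)])
    p = transition_distribution(g, 0, 1, Node2VecParams.bfs())
    assert p[0] == pytest.approx(5 / 5.2, abs=1e-12)
    assert p[2] == pytest.approx(0.2 / 5.2, abs=1e-12)


def test_transition_triangle_dfs_prefers_shared_neighbor():
    g = make_graph(3, [(0, 1), (1, 2), (0, 2)])
    p = transition_distribution(g, 0, 1, Node2VecParams.dfs())
    assert p[0] == pytest.approx(0.2 / 1.2, abs=1e-12)
    assert p[2] == pytest.approx(1.0 / 1.2, abs=1e-12)


def test_transition_matches_brute_force_on_50_random_cases():
    rng = np.random.default_rng(123)
    cases = 0
    while cases < 50:
        n = int(rng.integers(5, 30))
        mask = rng.random((n, n)) < 0.25
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if mask[i, j]]
        if not edges:
            continue
        g = make_graph(n, edges)
        u, v = edges[int(rng.integers(len(edges)))]
        params = PRESETS[cases % 3] if cases < 6 else Node2VecParams(
            return_weight=float(rng.uniform(0.1, 5)),
            explore_weight=float(rng.uniform(0.1, 5)))
        got = transition_distribution(g, u, v, params)
        want = _brute_force_transition(g, u, v, params)
        assert set(got) == set(want)
        for k in got:
            assert got[k] == pytest.approx(want[k], abs=1e-12)
        assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)
        cases += 1


def test_transition_errors():
    g = make_graph(3, [(0, 1)])
    with pytest.raises(ValueError, match="no neighbors"):
        transition_distribution(g, None, 2, Node2VecParams())
    with pytest.raises(ValueError, match="adjacent"):
        transition_distribution(g, 2, 0, Node2VecParams())


# -------------------------------------------------------------------- walks

def test_single_edge_walks_alternate():
    g = make_graph(2, [(0, 1)])
    walks = generate_walks(g, Node2VecParams(walk_length=4, walks_per_node=3, seed=5))
    for w in walks:
        assert list(w) in ([0, 1, 0, 1], [1, 0, 1, 0])


def test_walks_are_edge_consistent_and_counted(small_preset):
    _, g, _ = small_preset
    params = Node2VecParams.bfs(walks_per_node=1, walk_length=10, seed=2)
    walks = generate_walks(g, params)
    deg = g.degrees()
    assert walks.shape[0] == int((deg > 0).sum()) * params.walks_per_node
    rng = np.random.default_rng(0)
    for w in walks[rng.choice(len(walks), 50, replace=False)]:
        steps = w[w >= 0]
        for a, b in zip(steps[:-1], steps[1:]):
            assert g.has_edge(int(a), int(b))


def test_walk_empirical_frequencies_match_transition_distribution():
    rng = np.random.default_rng(3)
    mask = rng.random((10, 10)) < 0.4
    edges = [(i, j) for i in range(10) for j in range(i + 1, 10) if mask[i, j]]
    g = make_graph(10, edges)
    params = Node2VecParams.bfs(walks_per_node=70, walk_length=80, seed=9)
    walks = generate_walks(g, params)
    counts: dict = {}
    for w in walks:
        steps = w[w >= 0]
        for prev, curr, nxt in zip(steps[:-2], steps[1:-1], steps[2:]):
            counts.setdefault((int(prev), int(curr)), {}).setdefault(int(nxt), 0)
            counts[(int(prev), int(curr))][int(nxt)] += 1
    checked = 0
    for (prev, curr), obs in counts.items():
        n = sum(obs.values())
        if n < 500:
            continue
        expect = transition_distribution(g, prev, curr, params)
        for nxt, p in expect.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(obs.get(nxt, 0) / n - p) <= 3 * sd + 1e-9
        checked += 1
    assert checked >= 5


def test_walks_deterministic_given_seed():
    g = clique_pair(6)
    params = Node2VecParams(walk_length=20, walks_per_node=4, seed=11)
    assert np.array_equal(generate_walks(g, params), generate_walks(g, params))


def test_walks_require_an_edge():
    g = make_graph(3, [])
    with pytest.raises(ValueError, match="no edges"):
        generate_walks(g, Node2VecParams())


# ----------------------------------------------------------------- training

TOY = Node2VecParams.balanced(dim=10, walks_per_node=10, walk_length=30,
                              epochs=6, seed=21)


def test_skipgram_separates_disconnected_cliques():
    g = clique_pair(10)
    emb = embed_graph(g, TOY)
    intra, inter = clique_separation(emb.vectors, 10)
    assert intra > inter


def test_skipgram_loss_declines_over_training():
    g = clique_pair(10)
    emb = embed_graph(g, TOY)
    assert emb.loss_per_epoch[-1] < emb.loss_per_epoch[0]


def test_skipgram_barbell_centroids_separate():
    size = 8
    edges = []
    for base in (0, size):
        for i in range(size):
            for j in range(i + 1, size):
                edges.append((base + i, base + j))
    edges.append((size - 1, size))   # bridge
    g = make_graph(2 * size, edges)
    emb = embed_graph(g, Node2VecParams.balanced(
        dim=10, walks_per_node=12, walk_length=30, epochs=6, seed=8))
    a = emb.vectors[:size]
    b = emb.vectors[size:]
    gap = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
    disp_a = np.linalg.norm(a - a.mean(axis=0), axis=1).mean()
    disp_b = np.linalg.norm(b - b.mean(axis=0), axis=1).mean()
    assert gap > disp_a and gap > disp_b


def test_skipgram_deterministic_and_rejects_empty():
    g = clique_pair(5)
    walks = generate_walks(g, TOY)
    a = train_skipgram(walks, TOY, n_nodes=g.n_nodes)
    b = train_skipgram(walks, TOY, n_nodes=g.n_nodes)
    assert np.array_equal(a.vectors, b.vectors)
    with pytest.raises(ValueError, match="empty"):
        train_skipgram(np.empty((0, 5), dtype=np.int64), TOY)


def test_line_first_order_separates_cliques():
    g = clique_pair(10)
    emb = train_line(g, LINEParams(dim=10, order="first", seed=31))
    intra, inter = clique_separation(emb.vectors, 10)
    assert intra > inter


def test_line_second_order_places_shared_context_hubs_together():
    # two hubs sharing all ten leaves: identical neighborhoods
    edges = [(0, i) for i in range(2, 12)] + [(1, i) for i in range(2, 12)]
    g = make_graph(12, edges)
    emb = train_line(g, LINEParams(dim=8, order="second",
                                   total_samples=200_000, seed=32))
    v = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    s = v @ v.T
    np.fill_diagonal(s, -np.inf)
    assert s[0].argmax() == 1
    assert s[1].argmax() == 0


def test_line_deterministic_and_rejects_edgeless():
    g = clique_pair(5)
    p = LINEParams(dim=6, seed=33, total_samples=20_000)
    assert np.array_equal(train_line(g, p).vectors, train_line(g, p).vectors)
    with pytest.raises(ValueError, match="no edges"):
        train_line(make_graph(4, []), p)


def test_embedding_matrix_rejects_non_finite():
    bad = np.ones((3, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        EmbeddingMatrix(bad, "x", LINEParams(), 0)


# --------------------------------------------------------------- projection

def test_project_2d_contracts():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 10))
    P = project_2d(X, seed=1)
    assert P.shape == (40, 2) and np.isfinite(P).all()
    # degenerate input still projects
    P2 = project_2d(np.ones((10, 5)), seed=1)
    assert P2.shape == (10, 2) and np.isfinite(P2).all()
    with pytest.raises(ValueError, match="3 rows"):
        project_2d(np.ones((2, 5)), seed=1)


# -------------------------------------------------------------- persistence

def test_embedding_tsv_round_trip(tmp_path):
    g = clique_pair(4)
    emb = train_line(g, LINEParams(dim=4, seed=2, total_samples=10_000))
    save_embedding(emb, g.node_ids, tmp_path / "emb.tsv", tmp_path / "emb.json")
    ids, vec, meta = load_embedding(tmp_path / "emb.tsv", tmp_path / "emb.json")
    assert np.array_equal(ids, g.node_ids)
    assert np.allclose(vec, emb.vectors)
    assert meta["method"] == "line-first" and meta["params"]["dim"] == 4


def test_relabeling_preserves_embedding_quality():
    """Same structure under different node ids gives the same separation."""
    g1 = clique_pair(8)
    ids2 = [f"z{99 - i:03d}" for i in range(16)]   # reversed sort order
    g2 = make_graph(16, [tuple(e) for e in g1.edge_pairs], ids=ids2)
    p = Node2VecParams.balanced(dim=8, walks_per_node=10, walk_length=20,
                                epochs=5, seed=13)
    e1 = embed_graph(g1, p)
    e2 = embed_graph(g2, p)
    # dense index of g2 reverses the clique halves; separation is invariant
    i1 = clique_separation(e1.vectors, 8)
    i2 = clique_separation(e2.vectors, 8)
    assert i1[0] > i1[1] and i2[0] > i2[1]
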