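import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kglink.graph import connected_components
from kglink.split import (biased_specific_edge_split, connected_holdout,
                          degree_aware_negative_sample, false_negative_rate,
                          stratified_node_holdout, unbiased_specific_edge_split,
                          _cumulative_weights, _draw_nodes, _pair_keys)
from kglink.synthetic import (dense_target_spec, generate_kg,
                              MIRNA_DISEASE_EDGE_TYPE)

from conftest import make_graph


# --------------------------------------------------------- connected holdout

def test_triangle_holdout_keeps_train_connected():
    g = make_graph(3, [(0, 1), (1, 2), (0, 2)])
    split = connected_holdout(g, 1 / 3, seed=0)
    assert len(split.test_pairs) == 1
    assert connected_components(split.train_graph())[0] == 1
    split.check_invariants()


def test_tree_holdout_is_empty_with_warning():
    g = make_graph(3, [(0, 1), (1, 2)])
    with pytest.warns(UserWarning, match="forest"):
        split = connected_holdout(g, 0.4, seed=1)
    assert len(split.test_pairs) == 0
    assert len(split.train_pairs) == 2


def test_holdout_component_preservation_and_size_on_preset(small_preset):
    _, g, _ = small_preset
    n_src, _ = connected_components(g)
    target = round(0.3 * g.n_edges)
    for seed in range(10):
        split = connected_holdout(g, 0.3, seed=seed)
        assert connected_components(split.train_graph())[0] == n_src
        assert abs(len(split.test_pairs) - target) <= 1
        assert len(split.test_pairs) + len(split.train_pairs) == g.n_edges


@given(st.lists(st.tuples(st.integers(0, 24), st.integers(0, 24)),
                min_size=1, max_size=120), st.integers(0, 10_000))
@settings(derandomize=True, max_examples=40)
def test_holdout_invariants_on_random_graphs(pairs, seed):
    pairs = [(u, v) for u, v in pairs if u != v]
    if not pairs:
        return
    g = make_graph(25, pairs)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        split = connected_holdout(g, 0.3, seed=seed)
    split.check_invariants()


def test_holdout_bad_fraction():
    g = make_graph(3, [(0, 1)])
    with pytest.raises(ValueError, match="test_fraction"):
        connected_holdout(g, 1.5, seed=0)


# -------------------------------------------------------- stratified holdout

def test_stratified_counts_single_type():
    g = make_graph(10, [], types=["T"] * 10)
    (train, test), = stratified_node_holdout(g, 0.3, n_repeats=1, seed=0)
    assert len(test) == 3 and len(train) == 7


def test_stratified_counts_two_types():
    g = make_graph(110, [], types=["A"] * 100 + ["B"] * 10)
    (train, test), = stratified_node_holdout(g, 0.3, n_repeats=1, seed=0)
    types = g.node_types
    assert (types[test] == "A").sum() == 30
    assert (types[test] == "B").sum() == 3


def test_stratified_reproducible_and_repeats_differ():
    g = make_graph(60, [], types=["A"] * 30 + ["B"] * 30)
    runs1 = stratified_node_holdout(g, 0.3, n_repeats=5, seed=7)
    runs2 = stratified_node_holdout(g, 0.3, n_repeats=5, seed=7)
    for (a, b), (c, d) in zip(runs1, runs2):
        assert np.array_equal(a, c) and np.array_equal(b, d)
    assert any(not np.array_equal(runs1[0][1], runs1[i][1]) for i in range(1, 5))


def test_singleton_type_goes_to_train_with_warning():
    g = make_graph(11, [], types=["A"] * 10 + ["B"])
    with pytest.warns(UserWarning, match="single member"):
        (train, test), = stratified_node_holdout(g, 0.3, n_repeats=1, seed=0)
    b = np.flatnonzero(g.node_types == "B")[0]
    assert b in train and b not in test


# --------------------------------------------------------- negative sampling

def test_complete_graph_has_no_negatives():
    g = make_graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
    with pytest.raises(ValueError, match="shortfall"):
        degree_aware_negative_sample(g, 1, seed=0, max_rejections=50)


def test_star_raw_endpoint_marginal_is_degree_proportional():
    g = make_graph(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
    deg = g.degrees()
    nodes = np.flatnonzero(deg > 0)
    cum = _cumulative_weights(deg[nodes].astype(float))
    rng = np.random.default_rng(0)
    draws = _draw_nodes(rng, nodes, cum, 20_000)
    freq_center = float((draws == 0).mean())
    sd = np.sqrt(0.5 * 0.5 / 20_000)
    assert abs(freq_center - 0.5) <= 3 * sd


def test_negatives_are_valid_non_edges(small_preset):
    _, g, _ = small_preset
    excl = g.edge_pairs[:5]  # pretend these were already used elsewhere
    neg = degree_aware_negative_sample(g, 2000, exclusions=excl, seed=3)
    assert neg.shape == (2000, 2)
    keys = _pair_keys(neg, g.n_nodes)
    assert len(np.unique(keys)) == 2000
    assert not np.isin(keys, g.pair_keys()).any()
    assert np.all(neg[:, 0] != neg[:, 1])


def test_negative_sampling_deterministic():
    g = make_graph(30, [(i, (i + 1) % 30) for i in range(30)] +
                   [(i, (i + 5) % 30) for i in range(30)])
    a = degree_aware_negative_sample(g, 50, seed=9)
    b = degree_aware_negative_sample(g, 50, seed=9)
    assert np.array_equal(a, b)


# ------------------------------------------------------- false-negative rate

def test_fn_rate_arithmetic():
    g = make_graph(6, [(0, 1), (2, 3)])
    cand = np.array([[0, 1], [0, 2], [1, 3], [4, 5]])
    assert false_negative_rate(cand, g) == pytest.approx(25.0)
    assert false_negative_rate(np.array([[0, 3], [1, 4]]), g) == 0.0
    assert false_negative_rate(np.empty((0, 2), dtype=np.int64), g) == 0.0


def test_fn_rate_matches_naive_membership_oracle(small_preset):
    _, g, _ = small_preset
    rng = np.random.default_rng(5)
    cand = np.column_stack([rng.integers(0, g.n_nodes, 1000),
                            rng.integers(0, g.n_nodes, 1000)])
    cand = cand[cand[:, 0] != cand[:, 1]]
    edge_set = {(int(u), int(v)) for u, v in g.edge_pairs}
    naive = 100.0 * sum(
        ((min(u, v), max(u, v)) in edge_set) for u, v in cand) / len(cand)
    assert false_negative_rate(cand, g) == pytest.approx(naive)


# ------------------------------------------------------ specific-edge splits

def test_unbiased_split_invariants(small_preset):
    _, g, _ = small_preset
    fsplit, train_graph = unbiased_specific_edge_split(
        g, MIRNA_DISEASE_EDGE_TYPE, test_fraction=0.3, seed=1)
    fsplit.check_invariants(g, unbiased=True)
    assert false_negative_rate(fsplit.test_neg, g) == 0.0
    assert false_negative_rate(fsplit.train_neg, g) == 0.0
    # training graph: same node universe, only train edges, components kept
    assert train_graph.n_nodes == g.n_nodes
    assert train_graph.n_edges < g.n_edges
    assert connected_components(train_graph)[0] == connected_components(g)[0]
    # negative sizes mirror the positive split at ratio 1
    assert len(fsplit.train_neg) == len(fsplit.train_pos)
    assert len(fsplit.test_neg) == len(fsplit.test_pos)
    # positives all carry the target type's endpoint pattern
    n_target = int((g.typed_edges["edge_type"] == MIRNA_DISEASE_EDGE_TYPE).sum())
    assert len(fsplit.train_pos) + len(fsplit.test_pos) == n_target
    assert abs(len(fsplit.test_pos) - 0.3 * n_target) <= 0.05 * n_target


def test_unbiased_split_supports_10x_negative_ratio():
    g, _ = generate_kg(dense_target_spec(seed=2))
    fsplit, _ = unbiased_specific_edge_split(
        g, MIRNA_DISEASE_EDGE_TYPE, test_fraction=0.3, negative_ratio=10,
        seed=2, type_constrained=False)
    assert len(fsplit.test_neg) == 10 * len(fsplit.test_pos)
    fsplit.check_invariants(g, unbiased=True)


def test_type_constrained_negatives_respect_endpoint_types(small_preset):
    _, g, _ = small_preset
    fsplit, _ = unbiased_specific_edge_split(
        g, MIRNA_DISEASE_EDGE_TYPE, test_fraction=0.3, seed=4)
    mi = {"miRNA_c1", "miRNA_c2", "miRNA_c3"}
    di = {"disease_c1", "disease_c2", "disease_c3"}
    for u, v in fsplit.negative_pool:
        ts = {g.node_types[u], g.node_types[v]}
        assert ts & mi and ts & di


def test_too_few_target_edges_is_an_error():
    g = make_graph(4, [(0, 1), (2, 3)], edge_types=["rare", "common"])
    with pytest.raises(ValueError, match="at least 2 edges"):
        unbiased_specific_edge_split(g, "rare", seed=0)


def test_biased_split_leaks_on_dense_target_but_unbiased_does_not():
    """A dense typed block (density 0.3) makes the biased shortcut leak >5%."""
    fn_biased = []
    for seed in range(5):
        g, _ = generate_kg(dense_target_spec(seed=seed))
        fsplit_u, _ = unbiased_specific_edge_split(
            g, MIRNA_DISEASE_EDGE_TYPE, test_fraction=0.3, seed=seed)
        assert false_negative_rate(fsplit_u.test_neg, g) == 0.0
        _, _, diag = biased_specific_edge_split(
            g, MIRNA_DISEASE_EDGE_TYPE, test_fraction=0.3, seed=seed)
        assert diag["fn_percent_test"] >= 0.0
        fn_biased.append(diag["fn_percent_test"])
    assert min(fn_biased) > 5.0


def test_bridge_only_target_type_cannot_leak_even_biased():
    # all target-type edges are bridges, so they are forced into train and
    # no held-out positive exists to be sampled as a false negative
    edges, etypes = [], []
    for i in range(4):          # clique over type-A nodes 0..3
        for j in range(i + 1, 4):
            edges.append((i, j))
            etypes.append("aa")
    for b in range(4, 8):       # pendant type-B nodes, one bridge each
        edges.append((b - 4, b))
        etypes.append("ab")
    g = make_graph(8, edges, types=["A"] * 4 + ["B"] * 4, edge_types=etypes)
    fsplit, _, diag = biased_specific_edge_split(
        g, "ab", test_fraction=0.3, seed=0, type_constrained=True)
    assert len(fsplit.test_pos) == 0
    assert diag["fn_percent_test"] == 0.0
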