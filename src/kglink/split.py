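"""Connectivity-preserving holdouts and leakage-free negative sampling.

Edge-prediction benchmarks need two safeguards that common tooling gets
wrong:

* **Connected holdout** -- test edges must be removable without changing the
  number of connected components of the training graph, otherwise the
  embedding sees a structurally different graph.  This is guaranteed by
  keeping a random spanning forest inside the training split ("Connected
  Monte-Carlo" holdout).

* **Unbiased negatives** -- candidate negative pairs must be rejected against
  the *full* graph's edge set.  If they are rejected only against the
  training edges (the biased shortcut), held-out positive edges can be
  sampled as "negatives"; these false negatives contaminate training and
  evaluation.  The unbiased seven-step pipeline implemented by
  :func:`unbiased_specific_edge_split` guarantees a 0.00% false-negative rate
  among sampled negatives; :func:`biased_specific_edge_split` reproduces the
  biased shortcut for comparison and reports its leakage.

Negative endpoints are drawn independently with probability proportional to
full-graph degree, so sampled negatives match the endpoint-degree profile of
positive edges (a positive edge's endpoint is degree-biased by construction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .graph import KnowledgeGraph, connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSplit", "FilteredSplit", "connected_holdout",
    "stratified_node_holdout", "degree_aware_negative_sample",
    "unbiased_specific_edge_split", "biased_specific_edge_split",
    "false_negative_rate",
]


def _sub_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), *tags])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _pair_keys(pairs: np.ndarray, n_nodes: int) -> np.ndarray:
    if pairs.size == 0:
        return np.empty(0, dtype=np.int64)
    return pairs[:, 0].astype(np.int64) * n_nodes + pairs[:, 1].astype(np.int64)


@dataclass
class EdgeSplit:
    """Positive train/test edge split of a source graph.

    ``train_pairs``/``test_pairs`` are canonical dense-index pairs; the typed
    rows of each pair travel with it (``train_types``/``test_types`` align
    with the typed row arrays ``train_typed``/``test_typed``).  The training
    graph preserves the source graph's component count.
    """

    source: KnowledgeGraph
    train_pairs: np.ndarray
    test_pairs: np.ndarray
    train_typed: np.ndarray   # (n, 2) pairs, one row per typed edge
    train_types: np.ndarray
    test_typed: np.ndarray
    test_types: np.ndarray

    def train_graph(self) -> KnowledgeGraph:
        """Graph over the same node set containing only training edges."""
        return self.source.with_edges(self.train_typed, self.train_types)

    def check_invariants(self) -> None:
        n = self.source.n_nodes
        tr = set(_pair_keys(self.train_pairs, n).tolist())
        te = set(_pair_keys(self.test_pairs, n).tolist())
        full = set(self.source.pair_keys().tolist())
        assert tr | te == full, "train u test != E(source)"
        assert not (tr & te), "train n test != empty"
        n_comp_src, _ = connected_components(self.source)
        n_comp_tr, _ = connected_components(self.train_graph())
        assert n_comp_tr == n_comp_src, "component count changed"


@dataclass
class FilteredSplit:
    """Type-filtered positive/negative, train/test quadruple.

    All positive members carry the target edge type; negative train and test
    sets are disjoint canonical pairs.  Under the unbiased pipeline the
    negatives additionally intersect no edge of the full graph (the
    zero-false-negative guarantee).
    """

    target_edge_type: str
    train_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    test_neg: np.ndarray

    @property
    def negative_pool(self) -> np.ndarray:
        return np.vstack([self.train_neg, self.test_neg]) \
            if self.train_neg.size or self.test_neg.size \
            else np.empty((0, 2), dtype=np.int64)

    def check_invariants(self, g: KnowledgeGraph, unbiased: bool = True) -> None:
        n = g.n_nodes
        tr = set(_pair_keys(self.train_neg, n).tolist())
        te = set(_pair_keys(self.test_neg, n).tolist())
        assert not (tr & te), "negative train/test sets intersect"
        if unbiased:
            full = set(g.pair_keys().tolist())
            assert not ((tr | te) & full), "negative set contains a true edge"


# ------------------------------------------------------------------ holdouts

class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def connected_holdout(g: KnowledgeGraph, test_fraction: float,
                      seed: int = 0) -> EdgeSplit:
    """Connected Monte-Carlo edge holdout.

    A random spanning forest of ``g`` is always kept in the training split,
    so removing the test edges cannot increase the number of connected
    components.  The remaining (non-forest) edges are assigned at random so
    that ``|test|`` is as close as possible to ``test_fraction * |E|``
    without violating the forest constraint.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(_sub_seed(seed, 101))
    pairs = g.edge_pairs
    order = rng.permutation(len(pairs))
    uf = _UnionFind(g.n_nodes)
    forest_mask = np.zeros(len(pairs), dtype=bool)
    for i in order:
        if uf.union(int(pairs[i, 0]), int(pairs[i, 1])):
            forest_mask[i] = True
    spare = np.flatnonzero(~forest_mask)
    target = int(round(test_fraction * len(pairs)))
    if target > spare.size:
        target = spare.size
    if target == 0:
        warnings.warn("graph is (nearly) a forest: test split is empty")
    test_idx = rng.permutation(spare)[:target]
    test_mask = np.zeros(len(pairs), dtype=bool)
    test_mask[test_idx] = True

    n = g.n_nodes
    test_keys = np.sort(_pair_keys(pairs[test_mask], n))
    typed = g.typed_edges
    tp = typed[["u", "v"]].to_numpy(dtype=np.int64)
    tkeys = _pair_keys(tp, n)
    typed_in_test = np.isin(tkeys, test_keys, assume_unique=False)
    et = typed["edge_type"].to_numpy(dtype=object)
    return EdgeSplit(
        source=g,
        train_pairs=pairs[~test_mask], test_pairs=pairs[test_mask],
        train_typed=tp[~typed_in_test], train_types=et[~typed_in_test],
        test_typed=tp[typed_in_test], test_types=et[typed_in_test],
    )


def stratified_node_holdout(g: KnowledgeGraph, test_fraction: float,
                            n_repeats: int = 5, seed: int = 0,
                            nodes: np.ndarray | None = None,
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test node partitions, one per repeat.

    Within each node type the test share is within one node of
    ``test_fraction``; types with a single member go entirely to train (with
    a warning).  Restricting to a subset of dense indices via ``nodes`` keeps
    the stratification within that subset.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    pool = np.arange(g.n_nodes) if nodes is None else np.asarray(nodes)
    types = g.node_types[pool]
    out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(_sub_seed(seed, 202, rep))
        train, test = [], []
        for t in np.unique(types):
            members = pool[types == t]
            if members.size == 1:
                warnings.warn(f"node type {t!r} has a single member; kept in train")
                train.append(members)
                continue
            n_test = int(round(test_fraction * members.size))
            perm = rng.permutation(members)
            test.append(perm[:n_test])
            train.append(perm[n_test:])
        out.append((np.sort(np.concatenate(train)),
                    np.sort(np.concatenate(test)) if test else np.empty(0, np.int64)))
    return out


# -------------------------------------------------------- negative sampling

def _cumulative_weights(weights: np.ndarray) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        raise ValueError("no positive-degree nodes to sample from")
    return np.cumsum(weights / total)


def _draw_nodes(rng: np.random.Generator, nodes: np.ndarray,
                cum: np.ndarray, size: int) -> np.ndarray:
    """Raw degree-proportional endpoint draws (before any rejection)."""
    r = rng.random(size)
    return nodes[np.searchsorted(cum, r, side="right").clip(max=len(nodes) - 1)]


def degree_aware_negative_sample(
        g: KnowledgeGraph, n_samples: int,
        exclusions: np.ndarray | None = None, seed: int = 0,
        max_rejections: int = 100,
        side_a: np.ndarray | None = None, side_b: np.ndarray | None = None,
        allowed_type_pairs: Iterable[tuple[str, str]] | None = None,
        reject_keys: np.ndarray | None = None) -> np.ndarray:
    """Sample non-edges whose endpoint degrees mimic those of positive edges.

    Endpoints are drawn independently with probability proportional to their
    *full-graph* degree; candidate pairs are rejected if the endpoints
    coincide, the pair is an edge of the rejection set (the full graph's edge
    set by default), it appears in ``exclusions``, its endpoint types are not
    an allowed type pair, or it was already sampled.  Raises a shortfall
    error naming the achieved count if ``max_rejections * n_samples`` draws
    are exhausted (as happens on dense graphs with no free pairs).
    """
    if n_samples <= 0:
        return np.empty((0, 2), dtype=np.int64)
    deg = g.degrees()
    if (deg > 0).sum() < 2:
        raise ValueError("need at least 2 nodes of nonzero degree")
    n = g.n_nodes
    if side_a is None:
        side_a = np.flatnonzero(deg > 0)
    if side_b is None:
        side_b = np.flatnonzero(deg > 0)
    side_a = np.asarray(side_a)
    side_b = np.asarray(side_b)
    cum_a = _cumulative_weights(deg[side_a].astype(float))
    cum_b = _cumulative_weights(deg[side_b].astype(float))
    if reject_keys is None:
        reject_keys = g.pair_keys()
    reject_keys = np.sort(np.asarray(reject_keys, dtype=np.int64))
    excl = set() if exclusions is None else \
        set(_pair_keys(np.asarray(exclusions).reshape(-1, 2), n).tolist())

    allowed = None
    if allowed_type_pairs is not None:
        allowed = {tuple(sorted(p)) for p in allowed_type_pairs}
    types = g.node_types

    rng = np.random.default_rng(_sub_seed(seed, 303))
    chosen: list[int] = []
    chosen_set: set[int] = set()
    budget = max_rejections * n_samples
    attempts = 0
    while len(chosen) < n_samples:
        if attempts >= budget:
            raise ValueError(
                f"negative-sample shortfall: achieved {len(chosen)} of "
                f"{n_samples} after {attempts} draws")
        need = n_samples - len(chosen)
        size = min(max(256, 2 * need), budget - attempts)
        attempts += size
        u = _draw_nodes(rng, side_a, cum_a, size)
        v = _draw_nodes(rng, side_b, cum_b, size)
        lo = np.minimum(u, v)
        hi = np.maximum(u, v)
        ok = lo != hi
        if allowed is not None:
            ta, tb = types[lo], types[hi]
            ok &= np.fromiter(
                (tuple(sorted((a, b))) in allowed for a, b in zip(ta, tb)),
                dtype=bool, count=len(lo))
        keys = lo.astype(np.int64) * n + hi.astype(np.int64)
        pos = np.searchsorted(reject_keys, keys)
        is_edge = (pos < reject_keys.size) & (reject_keys[pos.clip(max=max(reject_keys.size - 1, 0))] == keys) \
            if reject_keys.size else np.zeros(len(keys), dtype=bool)
        ok &= ~is_edge
        for key in keys[ok]:
            k = int(key)
            if k in excl or k in chosen_set:
                continue
            chosen_set.add(k)
            chosen.append(k)
            if len(chosen) == n_samples:
                break
    arr = np.asarray(chosen, dtype=np.int64)
    return np.column_stack([arr // n, arr % n])


def false_negative_rate(candidate_negatives: np.ndarray,
                        g: KnowledgeGraph) -> float:
    """Percentage of candidate pairs that are actually edges of ``g``."""
    cand = np.asarray(candidate_negatives, dtype=np.int64).reshape(-1, 2)
    if cand.shape[0] == 0:
        logger.info("false_negative_rate: empty candidate set, returning 0.0")
        return 0.0
    lo = np.minimum(cand[:, 0], cand[:, 1])
    hi = np.maximum(cand[:, 0], cand[:, 1])
    keys = lo * g.n_nodes + hi
    ref = g.pair_keys()
    pos = np.searchsorted(ref, keys)
    hit = (pos < ref.size) & (ref[pos.clip(max=max(ref.size - 1, 0))] == keys) \
        if ref.size else np.zeros(len(keys), dtype=bool)
    return 100.0 * float(hit.sum()) / cand.shape[0]


# ------------------------------------------------- specific-edge pipelines

def _target_endpoint_type_pairs(g: KnowledgeGraph,
                                target_edge_type: str) -> set[tuple[str, str]]:
    t = g.typed_edges
    mask = t["edge_type"].to_numpy() == target_edge_type
    ta = g.node_types[t["u"].to_numpy()[mask]]
    tb = g.node_types[t["v"].to_numpy()[mask]]
    return {tuple(sorted((a, b))) for a, b in zip(ta, tb)}


def _filtered_positives(split: EdgeSplit, target: str) -> tuple[np.ndarray, np.ndarray]:
    tr_mask = split.train_types == target
    te_mask = split.test_types == target
    return split.train_typed[tr_mask], split.test_typed[te_mask]


def _specific_edge_split(g: KnowledgeGraph, target_edge_type: str,
                         test_fraction: float, negative_ratio: float,
                         seed: int, unbiased: bool, type_constrained: bool,
                         endpoint_type_pairs: Iterable[tuple[str, str]] | None = None,
                         ) -> tuple[FilteredSplit, KnowledgeGraph, dict]:
    n_target = int((g.typed_edges["edge_type"] == target_edge_type).sum())
    if n_target < 2:
        raise ValueError(
            f"need at least 2 edges of type {target_edge_type!r}, found {n_target}")
    if negative_ratio < 1:
        raise ValueError("negative_ratio must be >= 1")

    # steps 1-3: connected holdout on the FULL graph, then type filtering;
    # embedding happens on the training graph (the caller's job, step 2)
    split = connected_holdout(g, test_fraction, seed=_sub_seed(seed, 11))
    train_graph = split.train_graph()
    train_pos, test_pos = _filtered_positives(split, target_edge_type)

    # step 4: negative pool sampled degree-aware; unbiased mode rejects
    # against the FULL graph's edges, the biased shortcut only against the
    # filtered training edges
    n_tr = int(round(negative_ratio * len(train_pos)))
    n_te = int(round(negative_ratio * len(test_pos)))
    side_a = side_b = None
    allowed = None
    if type_constrained:
        allowed = {tuple(sorted(p)) for p in endpoint_type_pairs} \
            if endpoint_type_pairs is not None \
            else _target_endpoint_type_pairs(g, target_edge_type)
        all_types = {t for pair in allowed for t in pair}
        deg = g.degrees()
        members = np.flatnonzero(np.isin(g.node_types, list(all_types)) & (deg > 0))
        side_a = side_b = members
    reject = None
    if not unbiased:
        reject = np.sort(_pair_keys(train_pos, g.n_nodes))
    pool = degree_aware_negative_sample(
        g, n_tr + n_te, seed=_sub_seed(seed, 13),
        side_a=side_a, side_b=side_b, allowed_type_pairs=allowed,
        reject_keys=reject)

    # step 5: disjoint negative train/test partition mirroring the positive
    # proportions (the pool has no duplicates, so disjointness is structural)
    rng = np.random.default_rng(_sub_seed(seed, 17))
    perm = rng.permutation(len(pool))
    test_neg = pool[perm[:n_te]]
    train_neg = pool[perm[n_te:]]

    fsplit = FilteredSplit(target_edge_type=target_edge_type,
                           train_pos=train_pos, test_pos=test_pos,
                           train_neg=train_neg, test_neg=test_neg)
    diagnostics = {
        "fn_percent_test": false_negative_rate(test_neg, g),
        "fn_percent_train": false_negative_rate(train_neg, g),
        "n_train_pos": int(len(train_pos)), "n_test_pos": int(len(test_pos)),
        "n_train_neg": int(len(train_neg)), "n_test_neg": int(len(test_neg)),
    }
    return fsplit, train_graph, diagnostics


def unbiased_specific_edge_split(
        g: KnowledgeGraph, target_edge_type: str, test_fraction: float = 0.3,
        negative_ratio: float = 1, seed: int = 0,
        type_constrained: bool = True,
        endpoint_type_pairs: Iterable[tuple[str, str]] | None = None,
        ) -> tuple[FilteredSplit, KnowledgeGraph]:
    """Seven-step unbiased specific-edge split.

    Returns the filtered split and the training graph on which embeddings
    must be computed (using the full graph would leak test edges into the
    representation).  Negatives are rejected against the full graph's edge
    set, so the false-negative rate among them is exactly zero.  With
    ``type_constrained`` the negative endpoints are restricted to the target
    type's endpoint-type pairs (inferred from the observed typed edges unless
    given explicitly via ``endpoint_type_pairs``).
    """
    fsplit, train_graph, _ = _specific_edge_split(
        g, target_edge_type, test_fraction, negative_ratio, seed,
        unbiased=True, type_constrained=type_constrained,
        endpoint_type_pairs=endpoint_type_pairs)
    return fsplit, train_graph


def biased_specific_edge_split(
        g: KnowledgeGraph, target_edge_type: str, test_fraction: float = 0.3,
        negative_ratio: float = 1, seed: int = 0,
        type_constrained: bool = True,
        endpoint_type_pairs: Iterable[tuple[str, str]] | None = None,
        ) -> tuple[FilteredSplit, KnowledgeGraph, dict]:
    """Biased baseline: negatives rejected only against filtered train edges.

    Identical to the unbiased pipeline except for the rejection set, so any
    performance difference on the same seed is attributable to false-negative
    leakage.  The returned diagnostics report the percentage of sampled
    negative test (and train) edges that are actually present in the full
    graph.
    """
    return _specific_edge_split(
        g, target_edge_type, test_fraction, negative_ratio, seed,
        unbiased=False, type_constrained=type_constrained,
        endpoint_type_pairs=endpoint_type_pairs)
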