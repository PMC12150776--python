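"""Node embeddings for homogeneous graphs: node2vec and LINE.

Both methods learn a map ``f: G -> R^n`` placing each node at a vector so
that topologically close nodes are close in the embedding space, ignoring
node and edge types.  node2vec generates biased second-order random walks
(return and explore weights ``1/p`` and ``1/q``) and trains a skip-gram model
with negative sampling on the walk corpus; LINE optimizes first- or
second-order proximity by stochastic updates on uniformly sampled edges with
degree^(3/4) negative sampling.

Named node2vec presets: BFS-like (return_weight=5, explore_weight=0.2),
DFS-like (0.2, 5), and Balanced (1, 1), the latter being an unbiased
first-order walk in the DeepWalk style.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .graph import KnowledgeGraph

logger = logging.getLogger(__name__)

__all__ = [
    "Node2VecParams", "LINEParams", "EmbeddingMatrix",
    "transition_distribution", "generate_walks", "train_skipgram",
    "train_line", "embed_graph", "project_2d",
    "save_embedding", "load_embedding",
]


@dataclass(frozen=True)
class Node2VecParams:
    """node2vec + skip-gram hyperparameters.

    ``return_weight`` and ``explore_weight`` are the walk-bias weights
    (``1/p`` and ``1/q``): a high return weight keeps the walk near its
    origin (BFS-like), a high explore weight pushes it outward (DFS-like).
    """

    dim: int = 10
    return_weight: float = 1.0
    explore_weight: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 100
    window: int = 5
    negatives_per_target: int = 5
    epochs: int = 10
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.walks_per_node <= 0 or self.walk_length <= 0 \
                or self.window <= 0 or self.negatives_per_target <= 0 \
                or self.epochs <= 0:
            raise ValueError("integer hyperparameters must be positive")
        if self.return_weight <= 0 or self.explore_weight <= 0 \
                or self.learning_rate <= 0:
            raise ValueError("weights and learning rate must be positive")

    @classmethod
    def bfs(cls, **kw) -> "Node2VecParams":
        return cls(return_weight=5.0, explore_weight=0.2, **kw)

    @classmethod
    def dfs(cls, **kw) -> "Node2VecParams":
        return cls(return_weight=0.2, explore_weight=5.0, **kw)

    @classmethod
    def balanced(cls, **kw) -> "Node2VecParams":
        return cls(return_weight=1.0, explore_weight=1.0, **kw)


@dataclass(frozen=True)
class LINEParams:
    """LINE hyperparameters.

    ``order`` selects first-order (direct connectivity) or second-order
    (shared-neighborhood) proximity.  ``total_samples`` defaults to
    ``100 * |E|`` of the embedded graph when left as ``None``.
    """

    dim: int = 10
    order: str = "first"
    total_samples: int | None = None
    negatives_per_sample: int = 5
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("first", "second"):
            raise ValueError("order must be 'first' or 'second'")
        if self.dim <= 0 or self.negatives_per_sample <= 0 \
                or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.total_samples is not None and self.total_samples <= 0:
            raise ValueError("total_samples must be positive")


@dataclass
class EmbeddingMatrix:
    """Learned node vectors aligned with a graph's dense index."""

    vectors: np.ndarray
    method: str
    params: Node2VecParams | LINEParams
    seed: int
    loss_per_epoch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains NaN/Inf entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]


# -------------------------------------------------------------------- walks

def transition_distribution(g: KnowledgeGraph, prev: int | None, curr: int,
                            params: Node2VecParams) -> dict[int, float]:
    """Exact node2vec next-step distribution over ``neighbors(curr)``.

    With ``prev is None`` (first step) the distribution is uniform.  Weights:
    ``return_weight`` for the previous node, 1 for candidates adjacent to the
    previous node, ``explore_weight`` otherwise, normalized to sum to 1.
    """
    nbrs = g.neighbors(curr)
    if nbrs.size == 0:
        raise ValueError(f"node {curr} has no neighbors")
    if prev is None:
        p = 1.0 / nbrs.size
        return {int(v): p for v in nbrs}
    if not g.has_edge(prev, curr):
        raise ValueError("prev must be adjacent to curr")
    prev_nbrs = set(int(x) for x in g.neighbors(prev))
    weights = np.empty(nbrs.size)
    for i, cand in enumerate(nbrs):
        if cand == prev:
            weights[i] = params.return_weight
        elif int(cand) in prev_nbrs:
            weights[i] = 1.0
        else:
            weights[i] = params.explore_weight
    weights /= weights.sum()
    return {int(v): float(w) for v, w in zip(nbrs, weights)}


def generate_walks(g: KnowledgeGraph, params: Node2VecParams) -> np.ndarray:
    """Walk corpus: ``walks_per_node`` biased walks from every non-isolated node.

    Returns an ``(n_walks, walk_length)`` int64 array of dense node indices,
    padded with -1 (only possible for isolated-start truncation, which is
    excluded here).  Reproducible from ``params.seed``.
    """
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    adj = g.adjacency()
    deg = g.degrees()
    non_isolated = np.flatnonzero(deg > 0)
    n_skipped = g.n_nodes - non_isolated.size
    if n_skipped:
        logger.info("skipping %d isolated node(s) as walk starts", n_skipped)
    starts = np.repeat(non_isolated, params.walks_per_node)
    return _kernels.walk_kernel(
        adj.indptr.astype(np.int64), adj.indices.astype(np.int64), starts,
        params.walk_length, float(params.return_weight),
        float(params.explore_weight), params.seed % (2 ** 31))


def train_skipgram(corpus: np.ndarray, params: Node2VecParams,
                   n_nodes: int | None = None) -> EmbeddingMatrix:
    """Skip-gram with negative sampling on a walk corpus.

    The noise distribution is proportional to the corpus unigram frequency
    raised to 3/4.  Mean training loss per epoch is recorded on the result.
    """
    corpus = np.asarray(corpus, dtype=np.int64)
    if corpus.size == 0 or (corpus < 0).all():
        raise ValueError("empty walk corpus")
    if n_nodes is None:
        n_nodes = int(corpus.max()) + 1
    freq = np.bincount(corpus[corpus >= 0].ravel(), minlength=n_nodes).astype(float)
    noise_prob, noise_alias = _kernels.build_alias(freq ** 0.75)
    W, _, losses = _kernels.sgns_kernel(
        corpus, params.window, params.dim, n_nodes, params.epochs,
        params.negatives_per_target, params.learning_rate, noise_prob,
        noise_alias, (params.seed + 1) % (2 ** 31))
    return EmbeddingMatrix(W, "node2vec", params, params.seed,
                           loss_per_epoch=losses)


def train_line(g: KnowledgeGraph, params: LINEParams) -> EmbeddingMatrix:
    """LINE first- or second-order embedding of ``g``."""
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    pairs = g.edge_pairs
    total = params.total_samples if params.total_samples is not None \
        else 100 * g.n_edges
    noise_prob, noise_alias = _kernels.build_alias(g.degrees().astype(float) ** 0.75)
    W, _, = _kernels.line_kernel(
        pairs[:, 0].astype(np.int64), pairs[:, 1].astype(np.int64),
        params.order == "first", params.dim, g.n_nodes, int(total),
        params.negatives_per_sample, params.learning_rate, noise_prob,
        noise_alias, (params.seed + 2) % (2 ** 31))
    return EmbeddingMatrix(W, f"line-{params.order}", params, params.seed)


def embed_graph(g: KnowledgeGraph,
                params: Node2VecParams | LINEParams) -> EmbeddingMatrix:
    """Train the embedding selected by the parameter object's type."""
    if isinstance(params, Node2VecParams):
        walks = generate_walks(g, params)
        return train_skipgram(walks, params, n_nodes=g.n_nodes)
    if isinstance(params, LINEParams):
        return train_line(g, params)
    raise TypeError(f"unsupported params type {type(params)!r}")


def project_2d(emb: EmbeddingMatrix | np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE projection (a reporting utility; delegated to scikit-learn)."""
    from sklearn.manifold import TSNE

    X = emb.vectors if isinstance(emb, EmbeddingMatrix) else np.asarray(emb)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows to project")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 input dimensions")
    perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
    out = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="random").fit_transform(X)
    return np.asarray(out, dtype=np.float64)


# -------------------------------------------------------------- persistence

def save_embedding(emb: EmbeddingMatrix, node_ids: np.ndarray,
                   tsv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Persist vectors as TSV (node_id + one column per dimension) + metadata."""
    df = pd.DataFrame(emb.vectors, columns=[f"d{i}" for i in range(emb.dim)])
    df.insert(0, "node_id", node_ids)
    df.to_csv(tsv_path, sep="\t", index=False)
    if meta_path is not None:
        meta = {"method": emb.method, "seed": emb.seed,
                "params": asdict(emb.params)}
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def load_embedding(tsv_path: str | Path,
                   meta_path: str | Path | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load a persisted embedding; returns ``(node_ids, vectors, metadata)``."""
    df = pd.read_csv(tsv_path, sep="\t")
    ids = df["node_id"].to_numpy(dtype=object)
    vec = df.drop(columns="node_id").to_numpy(dtype=np.float64)
    meta: dict = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    return ids, vec, meta
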