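"""Typed, undirected, unweighted knowledge-graph data model and TSV I/O.

A :class:`KnowledgeGraph` is the single substrate of the whole pipeline: every
node carries a categorical node type, every edge a categorical edge type.  The
graph is undirected and unweighted; topology (degrees, components, random
walks) sees each node *pair* at most once, while type-addressed operations see
one typed edge per ``(pair, edge_type)`` combination, because biomedical KGs
routinely hold several typed relations between the same two entities.

Edges are stored in canonical form: endpoints ordered by dense integer index,
smaller first.  All set algebra on edges (holdouts, negative-sample rejection,
false-negative audits) operates on this canonical form, so intersection and
difference between edge sets are well defined regardless of the orientation in
which an edge was originally written.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeGraph",
    "ViewSelector",
    "load_graph",
    "write_graph",
    "connected_components",
    "degree",
    "filter_view",
]


def _canonicalize(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return the pair arrays with the smaller dense index first."""
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    return lo, hi


@dataclass(frozen=True)
class ViewSelector:
    """Selection of node and edge types inducing a subgraph (a *view*).

    ``None`` for either field means "keep all".  Selecting all types returns a
    graph equal to the input.
    """

    node_types: frozenset[str] | None = None
    edge_types: frozenset[str] | None = None

    @staticmethod
    def of(node_types: Iterable[str] | None = None,
           edge_types: Iterable[str] | None = None) -> "ViewSelector":
        nt = None if node_types is None else frozenset(node_types)
        et = None if edge_types is None else frozenset(edge_types)
        return ViewSelector(nt, et)


class KnowledgeGraph:
    """Typed undirected graph with a stable dense node index.

    Parameters
    ----------
    node_ids:
        Node identifiers (opaque strings).  The dense index is the position in
        this sequence *after sorting*, so it is reproducible from the node-id
        set alone.
    node_types:
        Node-type label per node id (aligned with ``node_ids`` before sorting).
    edges:
        ``(n, 2)`` integer array of dense-index endpoint pairs, or an iterable
        of ``(u, v)`` pairs; orientation is irrelevant.
    edge_types:
        Edge-type label per edge row.

    Notes
    -----
    Self-loops are rejected here (they are dropped, with a log line, by
    :func:`load_graph`).  Duplicate ``(pair, edge_type)`` rows collapse to one
    typed edge; duplicate pairs with different edge types are kept as parallel
    typed edges over a single topological edge.
    """

    def __init__(self, node_ids: Sequence[str], node_types: Sequence[str],
                 edges: np.ndarray | Iterable[tuple[int, int]],
                 edge_types: Sequence[str]):
        ids = np.asarray(node_ids, dtype=object)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids")
        order = np.argsort(ids, kind="stable")
        self._node_ids = ids[order]
        self._node_types = np.asarray(node_types, dtype=object)[order]
        self._index: dict[str, int] = {nid: i for i, nid in enumerate(self._node_ids)}

        edges = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                           dtype=np.int64).reshape(-1, 2)
        etypes = np.asarray(edge_types, dtype=object)
        if edges.shape[0] != etypes.shape[0]:
            raise ValueError("edges and edge_types length mismatch")
        if edges.size and (edges.min() < 0 or edges.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed in a KnowledgeGraph")

        lo, hi = _canonicalize(edges[:, 0], edges[:, 1])
        typed = pd.DataFrame({"u": lo, "v": hi, "edge_type": etypes})
        typed = typed.drop_duplicates().sort_values(
            ["u", "v", "edge_type"], kind="stable").reset_index(drop=True)
        self._typed = typed

        pairs = typed[["u", "v"]].drop_duplicates().to_numpy(dtype=np.int64)
        # lexicographic order of canonical pairs
        if pairs.size:
            o = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs = pairs[o]
        self._pairs = pairs
        self._pair_keys = np.sort(pairs[:, 0] * self.n_nodes + pairs[:, 1]) \
            if pairs.size else np.empty(0, dtype=np.int64)
        self._adj: sparse.csr_matrix | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self._node_ids)

    @property
    def n_edges(self) -> int:
        """Number of topological (pair-once) edges."""
        return self._pairs.shape[0]

    @property
    def n_typed_edges(self) -> int:
        return len(self._typed)

    @property
    def node_ids(self) -> np.ndarray:
        return self._node_ids

    @property
    def node_types(self) -> np.ndarray:
        """Node-type label per dense index."""
        return self._node_types

    @property
    def edge_pairs(self) -> np.ndarray:
        """``(n_edges, 2)`` canonical dense-index pairs, lexicographically sorted."""
        return self._pairs

    @property
    def typed_edges(self) -> pd.DataFrame:
        """Typed edge table with columns ``u``, ``v``, ``edge_type`` (canonical)."""
        return self._typed

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def pair_key(self, u: int, v: int) -> int:
        lo, hi = (u, v) if u < v else (v, u)
        return lo * self.n_nodes + hi

    def pair_keys(self) -> np.ndarray:
        """Sorted int64 keys ``u * n_nodes + v`` of all canonical pairs."""
        return self._pair_keys

    def has_edge(self, u: int | str, v: int | str) -> bool:
        """Orientation-independent topological edge membership."""
        if isinstance(u, str):
            u = self._index[u]
        if isinstance(v, str):
            v = self._index[v]
        key = self.pair_key(u, v)
        i = np.searchsorted(self._pair_keys, key)
        return bool(i < self._pair_keys.size and self._pair_keys[i] == key)

    # --------------------------------------------------------------- topology
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric binary CSR adjacency over the dense index (cached)."""
        if self._adj is None:
            n = self.n_nodes
            if self._pairs.size:
                u, v = self._pairs[:, 0], self._pairs[:, 1]
                data = np.ones(2 * len(u), dtype=np.int8)
                rows = np.concatenate([u, v])
                cols = np.concatenate([v, u])
                self._adj = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
            else:
                self._adj = sparse.csr_matrix((n, n), dtype=np.int8)
        return self._adj

    def degrees(self) -> np.ndarray:
        """Topological degree per dense index; isolated nodes have 0."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self._pairs.size:
            np.add.at(deg, self._pairs[:, 0], 1)
            np.add.at(deg, self._pairs[:, 1], 1)
        return deg

    def neighbors(self, u: int) -> np.ndarray:
        adj = self.adjacency()
        return adj.indices[adj.indptr[u]:adj.indptr[u + 1]]

    # ------------------------------------------------------------ derivatives
    def with_edges(self, edges: np.ndarray, edge_types: Sequence[str]) -> "KnowledgeGraph":
        """Same node set (and dense index) with a replacement edge set.

        Used to build training graphs for embedding: rows of the resulting
        embedding matrix stay aligned with the original graph's dense index.
        """
        return KnowledgeGraph(self._node_ids, self._node_types, edges, edge_types)

    def equals(self, other: "KnowledgeGraph") -> bool:
        return (np.array_equal(self._node_ids, other._node_ids)
                and np.array_equal(self._node_types, other._node_types)
                and self._typed.equals(other._typed))


# ---------------------------------------------------------------------- I/O

def load_graph(node_table_path: str | Path, edge_list_path: str | Path) -> KnowledgeGraph:
    """Load a typed undirected graph from the two-TSV interchange format.

    The node table must have columns ``node_id`` and ``node_type``; the edge
    list must have ``source``, ``target`` and ``edge_type``.  Self-loop rows
    are dropped (logged); duplicate rows and both orientations of the same
    typed pair collapse to one typed edge.  An edge referencing an unknown
    node id is a hard error naming the offending row.
    """
    nodes = pd.read_csv(node_table_path, sep="\t", dtype=str)
    for col in ("node_id", "node_type"):
        if col not in nodes.columns:
            raise ValueError(f"node table {node_table_path}: missing column {col!r}")
    edges = pd.read_csv(edge_list_path, sep="\t", dtype=str)
    for col in ("source", "target", "edge_type"):
        if col not in edges.columns:
            raise ValueError(f"edge list {edge_list_path}: missing column {col!r}")

    index = {nid: i for i, nid in enumerate(nodes["node_id"])}
    src = np.empty(len(edges), dtype=np.int64)
    dst = np.empty(len(edges), dtype=np.int64)
    for row, (s, t) in enumerate(zip(edges["source"], edges["target"])):
        if s not in index:
            raise ValueError(f"edge list row {row}: unknown node_id {s!r}")
        if t not in index:
            raise ValueError(f"edge list row {row}: unknown node_id {t!r}")
        src[row], dst[row] = index[s], index[t]

    loops = src == dst
    if loops.any():
        logger.info("dropped %d self-loop edge row(s)", int(loops.sum()))
    keep = ~loops
    # map provisional indices to the sorted dense index of the constructor
    ids = nodes["node_id"].to_numpy(dtype=object)
    g = KnowledgeGraph(ids, nodes["node_type"].to_numpy(dtype=object),
                       np.column_stack([src[keep], dst[keep]]),
                       edges["edge_type"].to_numpy(dtype=object)[keep])
    return g


def write_graph(g: KnowledgeGraph, node_table_path: str | Path,
                edge_list_path: str | Path) -> None:
    """Write ``g`` in the two-TSV interchange format (round-trips with load)."""
    pd.DataFrame({"node_id": g.node_ids, "node_type": g.node_types}).to_csv(
        node_table_path, sep="\t", index=False)
    t = g.typed_edges
    pd.DataFrame({
        "source": g.node_ids[t["u"].to_numpy()],
        "target": g.node_ids[t["v"].to_numpy()],
        "edge_type": t["edge_type"].to_numpy(),
    }).to_csv(edge_list_path, sep="\t", index=False)


# ------------------------------------------------------------------- queries

def connected_components(g: KnowledgeGraph) -> tuple[int, np.ndarray]:
    """Connected components of ``g``.

    Returns ``(count, labels)`` where ``labels[i]`` is the component of dense
    index ``i``; two nodes share a label iff a path joins them.
    """
    n_comp, labels = csgraph.connected_components(g.adjacency(), directed=False)
    return int(n_comp), labels


def degree(g: KnowledgeGraph) -> dict[str, int]:
    """Map node id -> topological degree (sum over the map equals ``2|E|``)."""
    deg = g.degrees()
    return {nid: int(d) for nid, d in zip(g.node_ids, deg)}


def filter_view(g: KnowledgeGraph, sel: ViewSelector) -> KnowledgeGraph:
    """Subgraph induced by the selected node and edge types.

    Nodes are restricted to the selected node types (isolated survivors are
    retained); typed edges are restricted to the selected edge types and to
    pairs whose both endpoints survive.  Unknown labels in the selector raise
    a warning and are ignored.
    """
    if sel.node_types is not None:
        unknown = sel.node_types - set(g.node_types)
        if unknown:
            warnings.warn(f"unknown node types in selector: {sorted(unknown)}")
    if sel.edge_types is not None:
        unknown = sel.edge_types - set(g.typed_edges["edge_type"])
        if unknown:
            warnings.warn(f"unknown edge types in selector: {sorted(unknown)}")

    if sel.node_types is None:
        node_mask = np.ones(g.n_nodes, dtype=bool)
    else:
        node_mask = np.isin(g.node_types, list(sel.node_types))
    kept_ids = g.node_ids[node_mask]
    kept_types = g.node_types[node_mask]
    old_to_new = np.full(g.n_nodes, -1, dtype=np.int64)
    # constructor re-sorts ids; precompute final indices to remap edges
    new_index = {nid: i for i, nid in enumerate(np.sort(kept_ids))}
    for nid, old in zip(g.node_ids, range(g.n_nodes)):
        if node_mask[old]:
            old_to_new[old] = new_index[nid]

    t = g.typed_edges
    emask = node_mask[t["u"].to_numpy()] & node_mask[t["v"].to_numpy()]
    if sel.edge_types is not None:
        emask &= np.isin(t["edge_type"].to_numpy(), list(sel.edge_types))
    kept = t[emask]
    edges = np.column_stack([old_to_new[kept["u"].to_numpy()],
                             old_to_new[kept["v"].to_numpy()]])
    return KnowledgeGraph(kept_ids, kept_types, edges,
                          kept["edge_type"].to_numpy(dtype=object))
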