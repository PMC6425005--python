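"""CLANS-style similarity clustering.

The all-vs-all hit set becomes an undirected graph whose edges carry
alignment P-values.  A force-directed layout (attraction along edges scaled
by -log10(P), uniform pairwise repulsion) embeds the graph in 2-D for the
cluster map; family calls come from a seed-and-grow "convex" clustering on
the graph topology alone, followed by the pruning rules (nodes outside the
focus taxa with no edge into them are dropped; isolated clusters smaller
than three sequences are excluded unless a conserved motif is registered
for them).
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SimilarityHit

UNASSIGNED = "unassigned"


@dataclass
class LayoutParams:
    """Force constants of the embedding (config-overridable)."""

    repulsion: float = 0.05
    maxmove: float = 0.1
    attraction_scale: float = 100.0  # a(i,j) = min(1, -log10(p)/scale)


@dataclass
class ClusterGraph:
    """All-vs-all similarity graph with optional layout and cluster labels."""

    nodes: list[tuple[str, str]]  # (record_id, taxon), insertion-ordered
    edges: list[tuple[int, int, float]]  # (i, j, pvalue), i < j, deduplicated
    coords: np.ndarray | None = None  # (n, 2)
    cluster_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for i, j, p in self.edges:
            if i == j:
                raise ValueError(f"self-edge on node {i}")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index_of(self, record_id: str) -> int:
        for i, (rid, _) in enumerate(self.nodes):
            if rid == record_id:
                return i
        raise KeyError(record_id)

    def degree(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.nodes]
        for i, j, _ in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def attraction(self, pvalue: float, params: LayoutParams | None = None) -> float:
        params = params or LayoutParams()
        if pvalue <= 0:
            return 1.0
        return min(1.0, -math.log10(pvalue) / params.attraction_scale)


def build_graph(
    hits: Iterable[SimilarityHit],
    p_cut: float = 1e-06,
    taxa: Mapping[str, str] | None = None,
    include_ids: Sequence[str] = (),
) -> ClusterGraph:
    """Build the similarity graph from deduplicated undirected hits.

    Nodes are all ids appearing in hits plus any ``include_ids`` (isolated
    candidates keep a node even without edges); an edge is kept when its
    P-value is at most ``p_cut``.  Reciprocal duplicates collapse to one edge
    retaining the best (smallest) P-value.
    """
    taxa = taxa or {}
    order: list[str] = []
    index: dict[str, int] = {}

    def add_node(rid: str) -> int:
        if rid not in index:
            if taxa and rid not in taxa:
                print(f"warning: no taxon for {rid!r}; using 'unknown'", file=sys.stderr)
            index[rid] = len(order)
            order.append(rid)
        return index[rid]

    for rid in include_ids:
        add_node(rid)
    best: dict[tuple[int, int], float] = {}
    for h in hits:
        i = add_node(h.query_id)
        j = add_node(h.subject_id)
        if i == j:
            continue
        p = h.pvalue
        if p > p_cut:
            continue
        key = (min(i, j), max(i, j))
        if key not in best or p < best[key]:
            best[key] = p
    nodes = [(rid, taxa.get(rid, "unknown")) for rid in order]
    edges = [(i, j, p) for (i, j), p in sorted(best.items())]
    return ClusterGraph(nodes=nodes, edges=edges)


def drop_unconnected_to_focus(graph: ClusterGraph, focus_taxa: Iterable[str]) -> ClusterGraph:
    """Drop non-focus nodes with no edge to any focus-taxon node.

    Focus-taxon nodes are never removed.  Mirrors the map-pruning rule that
    outgroup peptides failing to connect to the clade of interest are
    excluded.
    """
    focus = set(focus_taxa)
    adj = graph.adjacency()
    keep: list[int] = []
    for i, (rid, taxon) in enumerate(graph.nodes):
        if taxon in focus:
            keep.append(i)
            continue
        if any(graph.nodes[j][1] in focus for j in adj[i]):
            keep.append(i)
    return _subgraph(graph, keep)


def _subgraph(graph: ClusterGraph, keep: list[int]) -> ClusterGraph:
    remap = {old: new for new, old in enumerate(keep)}
    nodes = [graph.nodes[i] for i in keep]
    edges = [
        (remap[i], remap[j], p)
        for i, j, p in graph.edges
        if i in remap and j in remap
    ]
    out = ClusterGraph(nodes=nodes, edges=edges)
    if graph.coords is not None:
        out.coords = graph.coords[keep].copy()
    if graph.cluster_of:
        out.cluster_of = {
            remap[i]: c for i, c in graph.cluster_of.items() if i in remap
        }
    return out


def run_layout(
    graph: ClusterGraph,
    rounds: int = 20000,
    seed: int = 0,
    params: LayoutParams | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Force-directed 2-D embedding of the graph.

    Coordinates start uniform in [-1, 1]^2 from ``seed``.  Each round every
    node receives attractive force  a(i,j) * (x_j - x_i)  summed over its
    edges and repulsive force  rep * (x_i - x_k) / ||x_i - x_k||^2  summed
    over all other nodes; the per-round displacement is capped at
    ``maxmove``.  Deterministic given seed; the graph's ``coords`` are set
    and returned.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    params = params or LayoutParams()
    n = graph.n_nodes
    if n == 0:
        graph.coords = np.zeros((0, 2))
        return graph.coords
    if init is not None:
        x = np.array(init, dtype=float)
        if x.shape != (n, 2):
            raise ValueError(f"init must have shape ({n}, 2)")
    else:
        rng = np.random.RandomState(seed)
        x = rng.uniform(-1.0, 1.0, size=(n, 2))
    if n == 1:
        graph.coords = x
        return x
    ei = np.array([e[0] for e in graph.edges], dtype=int)
    ej = np.array([e[1] for e in graph.edges], dtype=int)
    w = np.array([graph.attraction(e[2], params) for e in graph.edges])
    for _ in range(rounds):
        force = np.zeros_like(x)
        if len(ei):
            d = x[ej] - x[ei]
            f = w[:, None] * d
            np.add.at(force, ei, f)
            np.add.at(force, ej, -f)
        diff = x[:, None, :] - x[None, :, :]  # x_i - x_k
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(dist2, np.inf)
        dist2 = np.maximum(dist2, 1e-12)
        force += params.repulsion * (diff / dist2[:, :, None]).sum(axis=1)
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        scale = np.where(norm > params.maxmove, params.maxmove / np.maximum(norm, 1e-300), 1.0)
        x = x + force * scale
    graph.coords = x
    return x


def convex_clusters(graph: ClusterGraph, min_linkage_fraction: float = 0.5) -> dict[int, str]:
    """Seed-and-grow clustering on graph topology.

    Seeds are taken in decreasing degree order (ties: node order).  From a
    seed, the cluster repeatedly absorbs the qualifying unassigned node with
    the most edges into the current members (qualifying: edges to at least
    ``min_linkage_fraction`` of them; ties by the candidate's triangle
    support — the number of neighbours it shares with the cluster's current
    neighbourhood — then node order), until a fixed point.  Densest-first
    growth with structural tie-breaking keeps weakly linked bystanders out
    until the cluster core is complete.  Nodes whose grown cluster is a
    singleton are reported as "unassigned"; assigned nodes are never
    revisited.
    """
    if not 0 < min_linkage_fraction <= 1:
        raise ValueError("min_linkage_fraction must be in (0,1]")
    adj = graph.adjacency()
    deg = graph.degree()
    n = graph.n_nodes
    assigned: dict[int, str] = {}
    cluster_idx = 0
    for seed in sorted(range(n), key=lambda i: (-deg[i], i)):
        if seed in assigned:
            continue
        members = [seed]
        member_set = {seed}
        neighbourhood = set(adj[seed]) - member_set
        while True:
            best_cand = -1
            best_key = (-1, -1)
            for cand in range(n):
                if cand in assigned or cand in member_set:
                    continue
                links = len(adj[cand] & member_set)
                if links < min_linkage_fraction * len(members):
                    continue
                key = (links, len(adj[cand] & neighbourhood))
                if key > best_key:
                    best_cand, best_key = cand, key
            if best_cand < 0:
                break
            members.append(best_cand)
            member_set.add(best_cand)
            neighbourhood |= adj[best_cand]
            neighbourhood -= member_set
        if len(members) == 1:
            assigned[seed] = UNASSIGNED
        else:
            label = f"cluster_{cluster_idx}"
            cluster_idx += 1
            for m in members:
                assigned[m] = label
    graph.cluster_of = assigned
    return assigned


def prune_clusters(
    graph: ClusterGraph,
    min_size: int = 3,
    conserved_motif_clusters: Iterable[str] = (),
) -> tuple[ClusterGraph, list[str]]:
    """Remove clusters smaller than ``min_size`` lacking a conserved motif.

    ``conserved_motif_clusters`` names clusters for which a recognisable
    conserved motif/domain has been registered externally; those survive
    regardless of size.  Unassigned nodes count as singleton clusters.
    Returns the pruned graph and the removed record ids.
    """
    if not graph.cluster_of and graph.n_nodes:
        raise ValueError("clusters not assigned; run convex_clusters first")
    flagged = set(conserved_motif_clusters)
    sizes: dict[str, int] = {}
    for i, c in graph.cluster_of.items():
        if c == UNASSIGNED:
            continue
        sizes[c] = sizes.get(c, 0) + 1
    keep: list[int] = []
    removed: list[str] = []
    for i, (rid, _) in enumerate(graph.nodes):
        c = graph.cluster_of.get(i, UNASSIGNED)
        size = 1 if c == UNASSIGNED else sizes[c]
        if size >= min_size or c in flagged:
            keep.append(i)
        else:
            removed.append(rid)
    return _subgraph(graph, keep), removed
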