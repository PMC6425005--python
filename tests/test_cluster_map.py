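"""Similarity graph, force-directed layout, convex clustering, pruning."""

import itertools
import random

import numpy as np
import pytest

from prospect import (
    SimilarityHit,
    build_graph,
    convex_clusters,
    drop_unconnected_to_focus,
    prune_clusters,
    run_layout,
)
from prospect.clustermap import UNASSIGNED, ClusterGraph


def hit(q, s, evalue):
    return SimilarityHit(q, s, 50.0, 10, 5, 0, 0, 10, 0, 10, evalue, 30.0)


def planted_block_graph(n_blocks=3, block_size=15, p_within=0.8, p_between=0.02, seed=0):
    rng = random.Random(seed)
    n = n_blocks * block_size
    nodes = [(f"n{i}", "Gastropoda") for i in range(n)]
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        same = i // block_size == j // block_size
        if rng.random() < (p_within if same else p_between):
            edges.append((i, j, 1e-08))
    return ClusterGraph(nodes=nodes, edges=edges)


class TestBuildGraph:
    def test_edge_present_below_p_cut(self):
        g = build_graph([hit("a", "b", 1e-07)], p_cut=1e-06)
        assert len(g.edges) == 1

    def test_edge_absent_above_p_cut(self):
        g = build_graph([hit("a", "b", 1e-05)], p_cut=1e-06)
        assert len(g.edges) == 0
        assert {rid for rid, _ in g.nodes} == {"a", "b"}

    def test_reciprocal_hits_collapse_to_one_edge_with_best_p(self):
        g = build_graph([hit("a", "b", 1e-07), hit("b", "a", 1e-09)], p_cut=1e-06)
        assert len(g.edges) == 1
        assert g.edges[0][2] == pytest.approx(1e-09, rel=1e-6)

    def test_isolated_ids_keep_nodes(self):
        g = build_graph([hit("a", "b", 1e-07)], include_ids=["lonely"])
        assert ("lonely", "unknown") in g.nodes


class TestFocusDrop:
    def graph(self):
        nodes = [("m1", "Gastropoda"), ("out_linked", "Chordata"), ("out_alone", "Chordata")]
        return ClusterGraph(nodes=nodes, edges=[(0, 1, 1e-08)])

    def test_linked_outgroup_node_is_retained(self):
        g = drop_unconnected_to_focus(self.graph(), {"Gastropoda"})
        assert {rid for rid, _ in g.nodes} == {"m1", "out_linked"}

    def test_isolated_outgroup_node_is_removed(self):
        g = drop_unconnected_to_focus(self.graph(), {"Gastropoda"})
        assert "out_alone" not in {rid for rid, _ in g.nodes}

    def test_focus_only_graph_unchanged(self):
        g = ClusterGraph(nodes=[("a", "Gastropoda"), ("b", "Gastropoda")], edges=[])
        out = drop_unconnected_to_focus(g, {"Gastropoda"})
        assert out.nodes == g.nodes


class TestLayout:
    def test_singleton_feels_no_force(self):
        g = ClusterGraph(nodes=[("a", "t")], edges=[])
        x0 = run_layout(g, rounds=1, seed=5).copy()
        x1 = run_layout(g, rounds=100, seed=5)
        assert x0 == pytest.approx(x1)

    def test_connected_pair_contracts(self):
        g = ClusterGraph(nodes=[("a", "t"), ("b", "t")], edges=[(0, 1, 1e-20)])
        rng = np.random.RandomState(7)
        init = rng.uniform(-1, 1, size=(2, 2))
        d0 = np.linalg.norm(init[0] - init[1])
        coords = run_layout(g, rounds=2000, seed=7, init=init)
        d1 = np.linalg.norm(coords[0] - coords[1])
        assert d1 < d0

    def test_deterministic_given_seed(self):
        g = planted_block_graph(seed=1)
        a = run_layout(g, rounds=50, seed=9).copy()
        b = run_layout(g, rounds=50, seed=9)
        assert (a == b).all()

    def test_translation_equivariance(self):
        g = ClusterGraph(
            nodes=[("a", "t"), ("b", "t"), ("c", "t")], edges=[(0, 1, 1e-08), (1, 2, 1e-10)]
        )
        rng = np.random.RandomState(3)
        init = rng.uniform(-1, 1, size=(3, 2))
        shift = np.array([2.5, -1.0])
        a = run_layout(g, rounds=200, seed=0, init=init)
        b = run_layout(g, rounds=200, seed=0, init=init + shift)
        assert b == pytest.approx(a + shift, abs=1e-8)

    def test_rounds_must_be_positive(self):
        g = ClusterGraph(nodes=[("a", "t")], edges=[])
        with pytest.raises(ValueError):
            run_layout(g, rounds=0)

    def test_blocks_separate_within_closer_than_between(self):
        g = planted_block_graph(seed=0)
        coords = run_layout(g, rounds=2000, seed=0)
        within, between = [], []
        for i, j in itertools.combinations(range(45), 2):
            d = np.linalg.norm(coords[i] - coords[j])
            (within if i // 15 == j // 15 else between).append(d)
        assert np.mean(within) < np.mean(between)


# --- brute-force re-implementation of the seed-and-grow rule ------------------

def brute_force_convex(nodes_n, edges, min_linkage=0.5):
    adj = {i: set() for i in range(nodes_n)}
    for i, j, _ in edges:
        adj[i].add(j)
        adj[j].add(i)
    degree = {i: len(adj[i]) for i in range(nodes_n)}
    assigned = {}
    label = 0
    for seed in sorted(range(nodes_n), key=lambda i: (-degree[i], i)):
        if seed in assigned:
            continue
        members = {seed}
        while True:
            hood = set().union(*(adj[m] for m in members)) - members
            candidates = [
                (len(adj[c] & members), len(adj[c] & hood), c)
                for c in range(nodes_n)
                if c not in assigned
                and c not in members
                and len(adj[c] & members) >= min_linkage * len(members)
            ]
            if not candidates:
                break
            nxt = max(candidates, key=lambda t: (t[0], t[1], -t[2]))[2]
            members.add(nxt)
        if len(members) == 1:
            assigned[seed] = UNASSIGNED
        else:
            for m in members:
                assigned[m] = f"cluster_{label}"
            label += 1
    return assigned


def canonical(assignment):
    """Cluster labels up to renaming: map each node to the sorted member set."""
    groups = {}
    for node, label in assignment.items():
        groups.setdefault(label, set()).add(node)
    return {
        node: (UNASSIGNED if label == UNASSIGNED else frozenset(groups[label]))
        for node, label in assignment.items()
    }


class TestConvexClusters:
    def test_triangle_forms_one_cluster(self):
        g = ClusterGraph(
            nodes=[("a", "t"), ("b", "t"), ("c", "t")],
            edges=[(0, 1, 1e-8), (0, 2, 1e-8), (1, 2, 1e-8)],
        )
        labels = set(convex_clusters(g).values())
        assert len(labels) == 1 and UNASSIGNED not in labels

    def test_two_disjoint_triangles_form_two_clusters(self):
        edges = [(0, 1, 1e-8), (0, 2, 1e-8), (1, 2, 1e-8),
                 (3, 4, 1e-8), (3, 5, 1e-8), (4, 5, 1e-8)]
        g = ClusterGraph(nodes=[(f"n{i}", "t") for i in range(6)], edges=edges)
        cl = convex_clusters(g)
        assert len({cl[i] for i in range(3)}) == 1
        assert len({cl[i] for i in range(3, 6)}) == 1
        assert cl[0] != cl[3]

    def test_exhaustive_small_graphs_match_brute_force(self):
        for n in range(1, 6):
            pairs = list(itertools.combinations(range(n), 2))
            for mask in range(2 ** len(pairs)):
                edges = [(i, j, 1e-8) for k, (i, j) in enumerate(pairs) if mask >> k & 1]
                g = ClusterGraph(nodes=[(f"n{i}", "t") for i in range(n)], edges=edges)
                got = convex_clusters(g)
                expected = brute_force_convex(n, edges)
                assert canonical(got) == canonical(expected), (n, edges)

    def test_random_larger_graphs_match_brute_force(self, rng):
        for _ in range(300):
            n = rng.randint(6, 7)
            edges = [
                (i, j, 1e-8)
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.4
            ]
            g = ClusterGraph(nodes=[(f"n{i}", "t") for i in range(n)], edges=edges)
            assert canonical(convex_clusters(g)) == canonical(brute_force_convex(n, edges))

    def test_recovers_planted_blocks_exactly(self):
        g = planted_block_graph(seed=0)
        cl = convex_clusters(g)
        blocks = [{i for i in range(b * 15, (b + 1) * 15)} for b in range(3)]
        labels = {frozenset(i for i, l in cl.items() if l == lab) for lab in set(cl.values())}
        assert {frozenset(b) for b in blocks} == labels

    def test_relabeling_invariance_on_structured_graph(self, rng):
        # the recovered partition must not depend on how nodes are numbered
        # (checked where graph structure, not index tie-breaking, decides)
        g1 = planted_block_graph(seed=4)
        n = g1.n_nodes
        perm = list(range(n))
        rng.shuffle(perm)
        edges2 = [(min(perm[i], perm[j]), max(perm[i], perm[j]), p)
                  for i, j, p in g1.edges]
        g2 = ClusterGraph(nodes=[(f"n{i}", "t") for i in range(n)], edges=edges2)
        c1, c2 = convex_clusters(g1), convex_clusters(g2)
        groups1 = {frozenset(perm[i] for i, l in c1.items() if l == lab)
                   for lab in set(c1.values()) if lab != UNASSIGNED}
        groups2 = {frozenset(i for i, l in c2.items() if l == lab)
                   for lab in set(c2.values()) if lab != UNASSIGNED}
        assert groups1 == groups2


class TestPruning:
    def pair_graph(self):
        g = ClusterGraph(nodes=[("a", "t"), ("b", "t")], edges=[(0, 1, 1e-8)])
        convex_clusters(g)
        return g

    def test_small_cluster_without_motif_is_removed(self):
        g, removed = prune_clusters(self.pair_graph(), min_size=3)
        assert g.n_nodes == 0 and set(removed) == {"a", "b"}

    def test_small_cluster_with_conserved_motif_is_retained(self):
        g0 = self.pair_graph()
        label = g0.cluster_of[0]
        g, removed = prune_clusters(g0, min_size=3, conserved_motif_clusters=[label])
        assert g.n_nodes == 2 and removed == []

    def test_three_node_cluster_survives_the_boundary(self):
        g = ClusterGraph(
            nodes=[("a", "t"), ("b", "t"), ("c", "t")],
            edges=[(0, 1, 1e-8), (0, 2, 1e-8), (1, 2, 1e-8)],
        )
        convex_clusters(g)
        pruned, removed = prune_clusters(g, min_size=3)
        assert pruned.n_nodes == 3 and removed == []
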