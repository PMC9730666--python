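import itertools

import numpy as np
import pytest

from hicends.graph import (
    Cluster,
    ScaffoldGraph,
    break_cycles,
    build_link_graph,
    canonicalize_cluster,
    extract_clusters,
    reciprocal_best_filter,
)


def table_from_pairs(pairs):
    """EndContactTable-like object over explicit cross-contig pair values."""

    class T:
        def __init__(self, pairs):
            self._pairs = pairs
            contigs = []
            for (e1, e2) in pairs:
                for e in (e1, e2):
                    if e[0] not in contigs:
                        contigs.append(e[0])
            self.contigs = contigs

        def pairs(self):
            for (e1, e2), v in self._pairs.items():
                yield e1, e2, v

    return T(pairs)


def test_build_link_graph_strict_cutoff():
    pairs = {
        ((("A", "tail")), ("B", "head")): 35.0,
        ((("A", "head")), ("B", "tail")): 1.0,
    }
    t = table_from_pairs(pairs)
    g = build_link_graph(t, cutoff=10)
    assert list(g.link_edges.values()) == [35.0]
    assert build_link_graph(t, cutoff=100).link_edges == {}
    # equality with the cutoff excludes the edge
    assert build_link_graph(t, cutoff=35).link_edges == {}


def exhaustive_reciprocal_best(edges):
    """Keep an edge iff strictly heavier than every other edge at both ends."""
    kept = {}
    for (a, b), w in edges.items():
        rivals = [
            w2 for e2, w2 in edges.items()
            if e2 != (a, b) and (a in e2 or b in e2)
        ]
        if all(w > r for r in rivals):
            kept[(a, b)] = w
    return kept


def test_reciprocal_best_triangle():
    e1, e2, e3 = ("A", "tail"), ("B", "head"), ("C", "head")
    edges = {(e1, e2): 50.0, (e1, e3): 40.0, (e2, e3): 30.0}
    g = ScaffoldGraph(contigs=["A", "B", "C"], link_edges=dict(edges))
    kept = reciprocal_best_filter(g).link_edges
    assert kept == {(e1, e2): 50.0}
    assert kept == exhaustive_reciprocal_best(edges)


def test_reciprocal_best_single_edge_kept():
    e1, e2 = ("A", "tail"), ("B", "head")
    g = ScaffoldGraph(contigs=["A", "B"], link_edges={(e1, e2): 5.0})
    assert reciprocal_best_filter(g).link_edges == {(e1, e2): 5.0}


def test_reciprocal_best_tie_drops_both():
    e1, e2, e3 = ("A", "tail"), ("B", "head"), ("C", "head")
    edges = {(e1, e2): 50.0, (e1, e3): 50.0}
    g = ScaffoldGraph(contigs=["A", "B", "C"], link_edges=edges)
    assert reciprocal_best_filter(g).link_edges == {}


def random_end_graph(rng, n_contigs, tie_prone=False):
    contigs = [f"c{k}" for k in range(n_contigs)]
    ends = [(c, s) for c in contigs for s in ("head", "tail")]
    edges = {}
    for a, b in itertools.combinations(range(len(ends)), 2):
        ea, eb = ends[a], ends[b]
        if ea[0] == eb[0]:
            continue
        if rng.random() < 0.4:
            w = float(rng.integers(1, 8)) if tie_prone else float(rng.integers(1, 1000))
            edges[(ea, eb)] = w
    return ScaffoldGraph(contigs=contigs, link_edges=edges)


@pytest.mark.parametrize("tie_prone", [False, True])
def test_reciprocal_best_matches_exhaustive_on_random_graphs(tie_prone):
    rng = np.random.default_rng(17 if tie_prone else 18)
    for _ in range(250):
        g = random_end_graph(rng, int(rng.integers(2, 7)), tie_prone)
        assert (
            reciprocal_best_filter(g).link_edges
            == exhaustive_reciprocal_best(g.link_edges)
        )


def is_acyclic(graph):
    neighbor = {}
    for a, b in graph.link_edges:
        neighbor[a] = b
        neighbor[b] = a
    seen = set()
    for contig in graph.contigs:
        if contig in seen:
            continue
        comp = {contig}
        stack = [contig]
        while stack:
            c = stack.pop()
            for side in ("head", "tail"):
                n = neighbor.get((c, side))
                if n and n[0] not in comp:
                    comp.add(n[0])
                    stack.append(n[0])
        seen |= comp
        if all((c, s) in neighbor for c in comp for s in ("head", "tail")):
            return False
    return True


def test_cycle_broken_at_minimum_weight_link():
    edges = {
        (("c1", "tail"), ("c2", "head")): 100.0,
        (("c2", "tail"), ("c3", "head")): 90.0,
        (("c1", "head"), ("c3", "tail")): 30.0,
    }
    g = ScaffoldGraph(contigs=["c1", "c2", "c3"], link_edges=edges)
    cleaned = break_cycles(g)
    assert (("c1", "head"), ("c3", "tail")) not in cleaned.link_edges
    assert len(cleaned.link_edges) == 2
    clusters = extract_clusters(cleaned, {})
    assert [c for c, _ in clusters[0].members] == ["c1", "c2", "c3"]


def test_acyclic_graph_unchanged_and_two_cycles_lose_one_edge_each():
    path = ScaffoldGraph(
        contigs=["a", "b"],
        link_edges={(("a", "tail"), ("b", "head")): 5.0},
    )
    assert break_cycles(path).link_edges == path.link_edges

    edges = {
        (("a", "tail"), ("b", "head")): 10.0,
        (("a", "head"), ("b", "tail")): 4.0,
        (("x", "tail"), ("y", "head")): 9.0,
        (("x", "head"), ("y", "tail")): 2.0,
    }
    g = ScaffoldGraph(contigs=["a", "b", "x", "y"], link_edges=edges)
    cleaned = break_cycles(g)
    assert len(cleaned.link_edges) == 2
    assert (("a", "head"), ("b", "tail")) not in cleaned.link_edges
    assert (("x", "head"), ("y", "tail")) not in cleaned.link_edges
    assert is_acyclic(cleaned)


def test_break_cycles_on_random_reciprocal_graphs_yields_paths():
    rng = np.random.default_rng(23)
    for _ in range(250):
        g = random_end_graph(rng, int(rng.integers(2, 7)))
        rb = reciprocal_best_filter(g)
        cleaned = break_cycles(rb)
        assert is_acyclic(cleaned)
        removed = set(rb.link_edges) - set(cleaned.link_edges)
        # removals only ever break cycles, one (minimal) edge per cycle
        for edge in removed:
            restored = ScaffoldGraph(
                contigs=list(cleaned.contigs),
                link_edges={**cleaned.link_edges, edge: rb.link_edges[edge]},
            )
            assert not is_acyclic(restored)


def test_orientation_rules_tail_head_and_tail_tail():
    edges = {
        (("c1", "tail"), ("c2", "head")): 10.0,
        (("c2", "tail"), ("c3", "tail")): 9.0,
    }
    g = ScaffoldGraph(contigs=["c1", "c2", "c3"], link_edges=edges)
    clusters = extract_clusters(g, {"c1": 3, "c2": 2, "c3": 1})
    assert clusters[0].members == [("c1", "+"), ("c2", "+"), ("c3", "-")]


def test_orientation_rules_head_head():
    g = ScaffoldGraph(
        contigs=["c1", "c2"],
        link_edges={(("c1", "head"), ("c2", "head")): 10.0},
    )
    clusters = extract_clusters(g, {"c1": 1, "c2": 1})
    assert clusters[0].members == [("c1", "-"), ("c2", "+")]


def test_no_links_yields_forward_singletons():
    g = ScaffoldGraph(contigs=["b", "a"], link_edges={})
    clusters = extract_clusters(g, {"a": 5, "b": 5})
    assert sorted(c.members[0] for c in clusters) == [("a", "+"), ("b", "+")]


def test_extraction_partitions_contigs_and_is_reversal_stable():
    rng = np.random.default_rng(31)
    for _ in range(100):
        g = random_end_graph(rng, int(rng.integers(2, 8)))
        cleaned = break_cycles(reciprocal_best_filter(g))
        lengths = {c: 10 for c in cleaned.contigs}
        clusters = extract_clusters(cleaned, lengths)
        placed = [c for cl in clusters for c in cl.contigs()]
        assert sorted(placed) == sorted(cleaned.contigs)
        assert sum(cl.total_length for cl in clusters) == 10 * len(cleaned.contigs)
        # a path walked from the other terminal is the same canonical cluster
        for cl in clusters:
            assert (
                canonicalize_cluster(
                    Cluster(members=list(cl.reversed_tokens()))
                ).tokens()
                == canonicalize_cluster(cl).tokens()
            )


def test_extract_rejects_unbroken_cycle():
    edges = {
        (("a", "tail"), ("b", "head")): 10.0,
        (("a", "head"), ("b", "tail")): 4.0,
    }
    g = ScaffoldGraph(contigs=["a", "b"], link_edges=edges)
    with pytest.raises(ValueError, match="circular"):
        extract_clusters(g, {})


def test_canonicalize_cluster():
    c = Cluster(members=[("B", "+"), ("A", "-")])
    canon = canonicalize_cluster(c)
    assert canon.members == [("A", "+"), ("B", "-")]
    assert canonicalize_cluster(canon).members == canon.members
    single = Cluster(members=[("A", "+")])
    assert canonicalize_cluster(single).members == [("A", "+")]
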