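"""Scaffolding graph construction, cleaning and cluster extraction.

Nodes are contig ends; the two ends of one contig are tied by an unbreakable
sister edge, and cross-contig link edges carry end-pair contact values above
a cutoff.  Cleaning keeps only reciprocal-best links and breaks any circular
path at its weakest link, leaving a disjoint union of simple paths; each path
is traversed to produce an ordered, oriented contig cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

from .ends import EndContactTable, EndKey

__all__ = [
    "ScaffoldGraph",
    "Cluster",
    "build_link_graph",
    "reciprocal_best_filter",
    "break_cycles",
    "extract_clusters",
    "canonicalize_cluster",
]


def _edge_key(end1: EndKey, end2: EndKey) -> Tuple[EndKey, EndKey]:
    return (end1, end2) if end1 <= end2 else (end2, end1)


def _sister(node: EndKey) -> EndKey:
    contig, side = node
    return (contig, "tail" if side == "head" else "head")


@dataclass
class ScaffoldGraph:
    """End-node graph: implicit sister edges plus weighted link edges."""

    contigs: List[str]
    link_edges: Dict[Tuple[EndKey, EndKey], float] = field(default_factory=dict)

    def incident(self, node: EndKey) -> List[Tuple[Tuple[EndKey, EndKey], float]]:
        return [(edge, w) for edge, w in self.link_edges.items() if node in edge]

    def link_degree(self, node: EndKey) -> int:
        return len(self.incident(node))

    def _neighbor_map(self) -> Dict[EndKey, EndKey]:
        """End -> linked end, requiring link degree <= 1 everywhere."""
        neighbor: Dict[EndKey, EndKey] = {}
        for a, b in self.link_edges:
            if a in neighbor or b in neighbor:
                raise ValueError("graph has a node with link degree > 1")
            neighbor[a] = b
            neighbor[b] = a
        return neighbor

    def copy(self) -> "ScaffoldGraph":
        return ScaffoldGraph(list(self.contigs), dict(self.link_edges))


def build_link_graph(table: EndContactTable, cutoff: float) -> ScaffoldGraph:
    """Keep cross-contig end pairs whose contact value strictly exceeds the cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    edges: Dict[Tuple[EndKey, EndKey], float] = {}
    for end1, end2, value in table.pairs():
        if value > cutoff:
            edges[_edge_key(end1, end2)] = value
    return ScaffoldGraph(contigs=table.contigs, link_edges=edges)


def reciprocal_best_filter(graph: ScaffoldGraph) -> ScaffoldGraph:
    """Keep a link iff it is the unique heaviest link at both of its endpoints.

    A tie at the maximum drops every tied edge: joining on an ambiguous best
    hit risks chimeric scaffolds.
    """
    best: Dict[EndKey, Tuple[float, int]] = {}  # node -> (max weight, count at max)
    for (a, b), w in graph.link_edges.items():
        for node in (a, b):
            if node not in best or w > best[node][0]:
                best[node] = (w, 1)
            elif w == best[node][0]:
                best[node] = (w, best[node][1] + 1)
    kept = {
        edge: w
        for edge, w in graph.link_edges.items()
        if all(best[n] == (w, 1) for n in edge)
    }
    return ScaffoldGraph(contigs=list(graph.contigs), link_edges=kept)


def _components(
    graph: ScaffoldGraph, neighbor: Dict[EndKey, EndKey]
) -> List[List[str]]:
    """Connected contig components under link edges (sister edges implicit)."""
    seen: Set[str] = set()
    comps: List[List[str]] = []
    for contig in graph.contigs:
        if contig in seen:
            continue
        comp = [contig]
        seen.add(contig)
        stack = [contig]
        while stack:
            c = stack.pop()
            for side in ("head", "tail"):
                nxt = neighbor.get((c, side))
                if nxt is not None and nxt[0] not in seen:
                    seen.add(nxt[0])
                    comp.append(nxt[0])
                    stack.append(nxt[0])
        comps.append(comp)
    return comps


def break_cycles(graph: ScaffoldGraph) -> ScaffoldGraph:
    """Remove the weakest link from every alternating sister/link cycle.

    Requires link degree <= 1 everywhere (reciprocal-best output).  A
    component is circular when every end of every member contig carries a
    link.  Ties at the minimum weight go to the edge with lexicographically
    smallest (contig, side) endpoints.
    """
    neighbor = graph._neighbor_map()
    removed: Set[Tuple[EndKey, EndKey]] = set()
    for comp in _components(graph, neighbor):
        is_cycle = all(
            (c, side) in neighbor for c in comp for side in ("head", "tail")
        )
        if not is_cycle:
            continue
        members = set(comp)
        cycle_edges = [
            edge for edge in graph.link_edges if edge[0][0] in members
        ]
        weakest = min(cycle_edges, key=lambda e: (graph.link_edges[e], e))
        removed.add(weakest)
    kept = {e: w for e, w in graph.link_edges.items() if e not in removed}
    return ScaffoldGraph(contigs=list(graph.contigs), link_edges=kept)


# ---------------------------------------------------------------------------
# clusters


@dataclass
class Cluster:
    """Ordered, oriented contig list for one scaffold."""

    members: List[Tuple[str, str]]  # (contig_id, "+" | "-")
    total_length: int = 0
    robustness: int = 0

    def contigs(self) -> List[str]:
        return [c for c, _ in self.members]

    def tokens(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(self.members)

    def reversed_tokens(self) -> Tuple[Tuple[str, str], ...]:
        flip = {"+": "-", "-": "+"}
        return tuple((c, flip[o]) for c, o in reversed(self.members))


def canonicalize_cluster(cluster: Cluster) -> Cluster:
    """Pick the lexicographically smaller of a cluster and its reversal.

    A scaffold read right-to-left with flipped strands is the same scaffold;
    canonicalization makes cluster units comparable across runs.
    """
    fwd = cluster.tokens()
    rev = cluster.reversed_tokens()
    members = list(min(fwd, rev))
    return Cluster(
        members=members,
        total_length=cluster.total_length,
        robustness=cluster.robustness,
    )


def _walk_path(
    start: str, outer_side: str, neighbor: Dict[EndKey, EndKey]
) -> List[Tuple[str, str]]:
    """Walk a simple path from a terminal contig, assigning orientations.

    ``outer_side`` is the free (unlinked) end of the start contig.  A contig
    whose link leaves its tail, or enters its head, is forward; otherwise
    reverse.  The two rules agree for interior contigs because entry and exit
    are sister ends.
    """
    members: List[Tuple[str, str]] = []
    current, entry_side = start, outer_side
    while True:
        exit_side = "tail" if entry_side == "head" else "head"
        nxt = neighbor.get((current, exit_side))
        if nxt is None:
            if members:  # last contig: orient by its entry side
                members.append((current, "+" if entry_side == "head" else "-"))
            else:  # isolated contig
                members.append((current, "+"))
            return members
        members.append((current, "+" if exit_side == "tail" else "-"))
        current, entry_side = nxt[0], nxt[1]


def extract_clusters(
    graph: ScaffoldGraph, lengths: Mapping[str, int]
) -> List[Cluster]:
    """Traverse every simple path into an ordered, oriented cluster.

    The graph must already be cleaned (link degree <= 1, no cycles).
    Isolated contigs become forward singletons.  Output order: total length
    descending, then first contig name.
    """
    neighbor = graph._neighbor_map()
    clusters: List[Cluster] = []
    for comp in _components(graph, neighbor):
        terminals = sorted(
            (c, side)
            for c in comp
            for side in ("head", "tail")
            if (c, side) not in neighbor
        )
        if not terminals:
            raise ValueError("circular path encountered; run break_cycles first")
        start, outer_side = terminals[0]
        members = _walk_path(start, outer_side, neighbor)
        if len(members) != len(comp):
            raise ValueError("inconsistent path; graph is not a union of simple paths")
        total = sum(lengths.get(c, 0) for c, _ in members)
        clusters.append(Cluster(members=members, total_length=total))
    clusters.sort(key=lambda c: (-c.total_length, c.members[0][0]))
    return clusters
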