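"""Search-based transition network construction and path queries.

Each sample is searched against all others for its top-k most similar
neighbors; hits at or above the direct-transition threshold become
undirected edges.  An edge exists when EITHER endpoint lists the other
among its kept hits (union rule): the construction procedure connects
every query with its matched samples, so an asymmetric hit — b in a's
top-k but not vice versa — still yields the edge.

Pairs below the threshold may still be connected through a chain of
direct transitions; the intermediate samples on such a shortest chain
are the "transfer samples" of an indirect transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .sampleset import SampleSet
from .similarity import (
    SimilarityMeasure,
    get_measure,
    pairwise_similarity_matrix,
    topk_search,
)

__all__ = [
    "TransitionNetwork",
    "TransitionPath",
    "build_network",
    "find_transition_path",
    "write_edge_list",
    "write_graphml",
    "read_graphml",
]


@dataclass
class TransitionNetwork:
    """Undirected sample graph whose edges are direct transitions.

    Edge attribute ``similarity`` stores the score that admitted the
    edge; by construction every edge similarity is >= ``T_dt``.
    """

    graph: nx.Graph
    T_dt: float
    k: int
    measure_name: str
    habitat: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_ranked(self, sample_id: str) -> list[tuple[str, float]]:
        """Neighbors by descending edge similarity, id ascending on ties."""
        if sample_id not in self.graph:
            raise KeyError(f"unknown sample {sample_id!r}")
        nbrs = [
            (n, float(self.graph.edges[sample_id, n]["similarity"]))
            for n in self.graph.neighbors(sample_id)
        ]
        nbrs.sort(key=lambda t: (-t[1], t[0]))
        return nbrs


@dataclass(frozen=True)
class TransitionPath:
    """A shortest chain of direct transitions between two samples."""

    nodes: tuple[str, ...]

    @property
    def length(self) -> int:
        """Number of steps (edges)."""
        return len(self.nodes) - 1

    @property
    def transfer_samples(self) -> tuple[str, ...]:
        """Intermediate samples carrying an indirect transition."""
        return self.nodes[1:-1]


def build_network(
    sset: SampleSet,
    measure: SimilarityMeasure | str,
    T_dt: float,
    k: int = 100,
    tree=None,
) -> TransitionNetwork:
    """Build the transition network by per-sample top-k search.

    For each sample the top-k hits are computed exhaustively; hits with
    score >= ``T_dt`` are kept and contribute edges under the union
    rule.  The result is independent of sample order because the
    per-query ranking breaks ties by ascending id.
    """
    if not (0.0 <= T_dt <= 1.0):
        raise ValueError("T_dt must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(measure, str):
        measure = get_measure(measure)
    matrix = pairwise_similarity_matrix(sset, measure, tree=tree)
    g = nx.Graph()
    g.add_nodes_from(sset.sample_ids)
    for sid in sset.sample_ids:
        hits = topk_search(sid, sset, measure, k=k, _matrix=matrix)
        for nbr, score in hits.hits:
            if score >= T_dt:
                g.add_edge(sid, nbr, similarity=float(score))
    return TransitionNetwork(
        graph=g, T_dt=T_dt, k=k, measure_name=measure.name,
        habitat=dict(sset.habitat),
    )


def find_transition_path(
    net: TransitionNetwork, a: str, b: str
) -> TransitionPath | None:
    """Minimum-step path between two samples, or None if disconnected.

    Steps are unweighted edge counts (breadth-first search): length 1
    is a direct transition, length >= 2 an indirect one routed through
    transfer samples.
    """
    for node in (a, b):
        if node not in net.graph:
            raise KeyError(f"unknown sample {node!r}")
    try:
        nodes = nx.shortest_path(net.graph, a, b)
    except nx.NetworkXNoPath:
        return None
    return TransitionPath(nodes=tuple(nodes))


def write_edge_list(net: TransitionNetwork, path) -> None:
    """TSV edge list: sample_a, sample_b, similarity (ids sorted)."""
    with open(path, "w") as fh:
        fh.write("sample_a\tsample_b\tsimilarity\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\t{net.graph.edges[a, b]['similarity']:.12g}\n")


def write_graphml(net: TransitionNetwork, path) -> None:
    g = net.graph.copy()
    g.graph.update(T_dt=net.T_dt, k=net.k, measure=net.measure_name)
    for sid, hab in net.habitat.items():
        if sid in g:
            g.nodes[sid]["habitat"] = hab
    nx.write_graphml(g, path)


def read_graphml(path) -> TransitionNetwork:
    g = nx.read_graphml(path)
    habitat = {
        n: d["habitat"] for n, d in g.nodes(data=True) if "habitat" in d
    }
    return TransitionNetwork(
        graph=g,
        T_dt=float(g.graph.get("T_dt", 0.0)),
        k=int(g.graph.get("k", 100)),
        measure_name=str(g.graph.get("measure", "braycurtis")),
        habitat=habitat,
    )
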