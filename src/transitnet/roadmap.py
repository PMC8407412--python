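"""Two-level minimum-spanning-tree roadmap of habitat transitions.

Within one closure, the minimum spanning tree over distances
``dist(a, b) = 1 - sim(a, b)`` is the acyclic subnetwork linking all
samples at the smallest total distance — the globally most probable
transition path.  Collapsing the sample-level MST to habitats gives a
second-level graph whose edge (h_i, h_j) carries the mean distance of
the first-level MST edges joining the two habitats; the MST of that
graph is the dispersal roadmap.

Significance of the roadmap is assessed by permutation: each roadmap
edge's distance is replaced by that of a uniformly drawn network edge
connecting the same habitat pair, and the total distance of the
permuted roadmap is compared with the observed one.  The roadmap is
called significant when its total distance beats 99% of permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .closures import Closure
from .network import TransitionNetwork
from .sampleset import MOCK_LABEL

__all__ = [
    "SampleMst",
    "HabitatRoadmap",
    "sample_mst",
    "habitat_roadmap",
    "roadmap_significance",
    "write_roadmap_tsv",
    "write_roadmap_dot",
]


@dataclass(frozen=True)
class SampleMst:
    """First-level MST: edges (a, b, dist) spanning one closure."""

    edges: tuple[tuple[str, str, float], ...]
    total_distance: float

    @property
    def n_nodes(self) -> int:
        nodes = {a for a, _, _ in self.edges} | {b for _, b, _ in self.edges}
        return len(nodes)


@dataclass(frozen=True)
class HabitatRoadmap:
    """Second-level MST over habitats.

    Each edge carries the mean distance of its supporting first-level
    MST edges and their count; ``p_value`` is filled in by
    :func:`roadmap_significance`.
    """

    edges: tuple[tuple[str, str, float, int], ...]
    total_distance: float
    habitats: tuple[str, ...]
    n_components: int = 1
    p_value: float | None = None


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _kruskal(nodes, weighted_edges):
    """Kruskal with deterministic ties: (dist, smaller id pair).

    Returns the minimum spanning forest edges, sorted the same way.
    """
    uf = _UnionFind(nodes)
    chosen = []
    for a, b, d in sorted(
        (tuple(sorted((a, b))) + (d,) for a, b, d in weighted_edges),
        key=lambda e: (e[2], e[0], e[1]),
    ):
        if uf.union(a, b):
            chosen.append((a, b, d))
    return chosen


def sample_mst(
    net: TransitionNetwork | nx.Graph,
    closure: Closure | set[str] | None = None,
) -> SampleMst:
    """Minimum spanning tree of one closure on dist = 1 - similarity.

    Ties are broken by (distance, lexicographic id pair) so the tree is
    deterministic.  The closure must be connected within the network.
    """
    g = net.graph if isinstance(net, TransitionNetwork) else net
    if closure is not None:
        members = closure.members if isinstance(closure, Closure) else set(closure)
        g = g.subgraph(members)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes for a spanning tree")
    edges = [
        (a, b, 1.0 - float(d["similarity"])) for a, b, d in g.edges(data=True)
    ]
    chosen = _kruskal(list(g.nodes), edges)
    if len(chosen) != g.number_of_nodes() - 1:
        raise ValueError(
            "closure is disconnected in the network; run per closure"
        )
    return SampleMst(
        edges=tuple(chosen),
        total_distance=float(sum(d for _, _, d in chosen)),
    )


def habitat_roadmap(
    mst: SampleMst,
    habitats: dict[str, str],
) -> HabitatRoadmap:
    """Collapse a sample-level MST into the habitat-level roadmap.

    The habitat graph has an edge (h_i, h_j) iff the sample MST holds
    at least one inter-habitat edge between them, weighted by the mean
    of those edges' distances; its MST is the roadmap.  Mock samples
    are excluded.  A disconnected habitat graph yields the minimum
    spanning forest with a warning.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    habs: set[str] = set()
    for a, b, d in mst.edges:
        try:
            ha, hb = habitats[a], habitats[b]
        except KeyError as exc:
            raise KeyError(f"MST node without habitat label: {exc}") from None
        if MOCK_LABEL in (ha, hb):
            continue
        habs.update((ha, hb))
        if ha == hb:
            continue
        key = tuple(sorted((ha, hb)))
        sums[key] = sums.get(key, 0.0) + d
        counts[key] = counts.get(key, 0) + 1
    if len(habs) < 2:
        raise ValueError("need at least 2 habitats for a roadmap")
    gprime = [(a, b, sums[(a, b)] / counts[(a, b)]) for a, b in sums]
    chosen = _kruskal(sorted(habs), gprime)
    n_comp = len(habs) - len(chosen)
    if n_comp > 1:
        warnings.warn(
            f"habitat graph is disconnected ({n_comp} components); "
            "returning a minimum spanning forest", stacklevel=2,
        )
    edges = tuple(
        (a, b, d, counts[(a, b)]) for a, b, d in chosen
    )
    return HabitatRoadmap(
        edges=edges,
        total_distance=float(sum(d for _, _, d in chosen)),
        habitats=tuple(sorted(habs)),
        n_components=n_comp,
    )


def roadmap_significance(
    roadmap: HabitatRoadmap,
    net: TransitionNetwork,
    habitats: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value of the roadmap's total distance.

    Each permutation replaces every roadmap edge's distance with that
    of a uniformly chosen direct-transition edge between the same two
    habitats, drawn from the full network.  p = (#{perm_total <=
    roadmap_total} + 1) / (n_perm + 1); ties count against
    significance.
    """
    hab = habitats if habitats is not None else net.habitat
    # candidate distance pools per habitat pair
    pools: dict[tuple[str, str], list[float]] = {
        tuple(sorted((a, b)))[:2]: [] for a, b, _, _ in roadmap.edges
    }
    wanted = set(pools)
    for a, b, d in net.graph.edges(data=True):
        key = tuple(sorted((hab[a], hab[b])))
        if key in wanted:
            pools[key].append(1.0 - float(d["similarity"]))
    empty = [k for k, v in pools.items() if not v]
    if empty:
        raise ValueError(
            f"no network edges between habitat pair(s) {empty}; "
            "cannot permute"
        )
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(pools[tuple(sorted((a, b)))])
              for a, b, _, _ in roadmap.edges]
    totals = np.zeros(n_perm)
    for arr in arrays:
        totals += arr[rng.integers(0, arr.size, size=n_perm)]
    hits = int(np.count_nonzero(totals <= roadmap.total_distance))
    return (hits + 1) / (n_perm + 1)


def write_roadmap_tsv(roadmap: HabitatRoadmap, path) -> None:
    with open(path, "w") as fh:
        fh.write("habitat_a\thabitat_b\tmean_dist\tn_support_edges\n")
        for a, b, d, c in roadmap.edges:
            fh.write(f"{a}\t{b}\t{d:.12g}\t{c}\n")


def write_roadmap_dot(roadmap: HabitatRoadmap, path) -> None:
    """Graphviz DOT export for rendering the roadmap."""
    with open(path, "w") as fh:
        fh.write("graph roadmap {\n")
        for h in roadmap.habitats:
            fh.write(f'  "{h}";\n')
        for a, b, d, c in roadmap.edges:
            fh.write(
                f'  "{a}" -- "{b}" [label="{d:.4f}", weight={c}];\n'
            )
        fh.write("}\n")
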