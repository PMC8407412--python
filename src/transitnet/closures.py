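"""Transitive closures of the network, and bridging separated closures.

A closure is a maximal set of samples in which every pair is linked by
direct or indirect transitions — i.e. a connected component of the
transition network ("fully connected" in the mutual-reachability
sense, not a clique).  The largest closure is flagged as the main
closure; its fraction of all nodes is the headline connectivity
statistic of the network.

Two closures that a local dataset leaves separate may still be linked
through samples of an external reference collection: every member of
each closure is searched against the reference, above-threshold hits
are collected per side, and any hit shared by both sides is a transfer
sample that bridges the closures.  When no shared hit exists each side
is extended by its own hits and the search repeats; exhaustion without
overlap means the reference holds no transfer node for this pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .network import TransitionNetwork
from .sampleset import SampleSet
from .similarity import SimilarityMeasure, get_measure, topk_search

__all__ = ["Closure", "transitive_closures", "main_closure_fraction",
           "bridge_closures"]


@dataclass(frozen=True)
class Closure:
    """One maximal mutually-reachable set of samples."""

    members: frozenset[str]
    is_main: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def transitive_closures(net: TransitionNetwork | nx.Graph) -> list[Closure]:
    """Partition the node set into closures, largest first.

    Exactly one closure is flagged main: the largest, ties broken by
    the smallest lexicographic member id.  Isolated nodes form
    singleton closures.
    """
    g = net.graph if isinstance(net, TransitionNetwork) else net
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        Closure(members=c, is_main=(i == 0)) for i, c in enumerate(comps)
    ]


def main_closure_fraction(net: TransitionNetwork | nx.Graph) -> float:
    """Fraction of all nodes held by the main closure (0 for empty)."""
    g = net.graph if isinstance(net, TransitionNetwork) else net
    if g.number_of_nodes() == 0:
        return 0.0
    closures = transitive_closures(net)
    return closures[0].size / g.number_of_nodes()


def _side_hits(
    side: SampleSet, reference: SampleSet, measure, T_dt: float,
    k: int, tree,
) -> set[str]:
    """Above-threshold top-k reference hits for every member of one side."""
    pool = side.merge(reference)
    ref_ids = set(reference.profiles)
    hits: set[str] = set()
    for sid in side.sample_ids:
        ranked = topk_search(sid, pool, measure, k=k, tree=tree)
        for nbr, score in ranked.hits:
            if nbr in ref_ids and score >= T_dt:
                hits.add(nbr)
    return hits


def bridge_closures(
    samples: SampleSet,
    closure_a: Closure | set[str],
    closure_b: Closure | set[str],
    reference: SampleSet,
    measure: SimilarityMeasure | str = "braycurtis",
    *,
    T_dt: float,
    k: int = 100,
    max_rounds: int = 5,
    tree=None,
) -> set[str]:
    """Find reference transfer samples linking two separated closures.

    Round 1 searches every closure member against *reference* and keeps
    hits with similarity >= ``T_dt``; the intersection of the two
    sides' hit sets are the transfer samples.  With no intersection
    each side absorbs its hits and the search repeats, up to
    ``max_rounds``.  An empty return means no sample of the reference
    can act as a transfer node between these closures.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    if isinstance(measure, str):
        measure = get_measure(measure)
    ids_a = set(closure_a.members if isinstance(closure_a, Closure) else closure_a)
    ids_b = set(closure_b.members if isinstance(closure_b, Closure) else closure_b)
    if ids_a & ids_b:
        raise ValueError("closures are not disjoint")
    overlap = (ids_a | ids_b) & set(reference.profiles)
    if overlap:
        warnings.warn(
            f"removing {len(overlap)} reference samples that already belong "
            "to a closure", stacklevel=2,
        )
        reference = reference.subset(set(reference.profiles) - overlap)
    side_a = samples.subset(ids_a)
    side_b = samples.subset(ids_b)
    ref_ids = set(reference.profiles)
    ext_a: set[str] = set()  # reference samples absorbed into side A
    ext_b: set[str] = set()
    for _ in range(max_rounds):
        pool_a = ref_ids - ext_a
        pool_b = ref_ids - ext_b
        hits_a = (
            _side_hits(side_a, reference.subset(pool_a), measure, T_dt, k, tree)
            if pool_a else set()
        )
        hits_b = (
            _side_hits(side_b, reference.subset(pool_b), measure, T_dt, k, tree)
            if pool_b else set()
        )
        # the bridge is complete once the extended sides share any
        # reference sample; every absorbed sample on either side of the
        # meeting point is part of the transfer chain
        transfer = (hits_a | ext_a) & (hits_b | ext_b)
        if transfer:
            return transfer | ext_a | ext_b | (hits_a & hits_b)
        if not hits_a and not hits_b:
            return set()
        ext_a |= hits_a
        ext_b |= hits_b
        if hits_a:
            side_a = side_a.merge(reference.subset(hits_a))
        if hits_b:
            side_b = side_b.merge(reference.subset(hits_b))
    return set()
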