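"""Network size, degree structure, robustness, and habitat transition
frequencies.

Shortest "transition steps" are unweighted edge counts — one step per
direct transition — even though edges carry similarities; the mean and
maximum (diameter) over all pairs of a closure measure how tightly the
collection is knit.  Degree structure is summarized by the log-log
linearity of the degree distribution: a power law P(k) ~ k^(-gamma)
gives a straight line of slope -gamma, and the Pearson correlation of
log10 P(k) against log10 k is the scale-freeness diagnostic.
Robustness is probed by deleting random node subsets and re-measuring
main-closure coverage and step statistics on the residual network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .closures import Closure, main_closure_fraction, transitive_closures
from .network import TransitionNetwork
from .sampleset import MOCK_LABEL

__all__ = [
    "StepStats",
    "DegreeFit",
    "TransitionFrequencies",
    "step_stats",
    "degree_histogram",
    "scalefree_fit",
    "robustness_experiment",
    "transition_frequencies",
]


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, TransitionNetwork) else net


@dataclass(frozen=True)
class StepStats:
    """Shortest-step statistics over the pairs of one closure."""

    mean_steps: float
    diameter: int
    histogram: dict[int, int]
    n_pairs: int
    sampled: bool = False
    seed: int | None = None
    #: with sampled pairs the diameter is only a lower bound
    diameter_exact: bool = True


@dataclass(frozen=True)
class DegreeFit:
    """Least-squares line of log10 P(k) on log10 k over degrees k >= 1."""

    histogram: dict[int, int]
    pearson_r: float
    slope: float
    intercept: float
    n_points: int


@dataclass(frozen=True)
class TransitionFrequencies:
    """Mean direct transitions per sample, within and between habitats.

    ``within[h]`` counts both endpoints of every within-habitat edge
    (each edge is a transition available to each of its samples);
    ``between[h]`` counts edges with exactly one endpoint in h.  The
    paired two-sided t-test compares within vs between across
    habitats.
    """

    within: dict[str, float]
    between: dict[str, float]
    n_samples: dict[str, int]
    t_statistic: float = float("nan")
    p_value: float = float("nan")


def step_stats(
    net: TransitionNetwork | nx.Graph,
    closure: Closure | set[str] | None = None,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> StepStats:
    """Mean shortest steps, diameter, and step histogram in a closure.

    With ``max_pairs`` unset all pairs are measured via breadth-first
    search from every member; otherwise a seeded uniform sample of
    pairs is used and the diameter is flagged as a lower bound.
    """
    g = _graph(net)
    if closure is None:
        closure = transitive_closures(g)[0] if g.number_of_nodes() else set()
    members = sorted(
        closure.members if isinstance(closure, Closure) else closure
    )
    if len(members) < 2:
        raise ValueError("closure must have at least 2 members")
    unknown = [m for m in members if m not in g]
    if unknown:
        raise KeyError(f"closure members not in network: {unknown[:5]}")
    sub = g.subgraph(members)
    hist: dict[int, int] = {}
    total = 0
    n_pairs = 0
    if max_pairs is None:
        for i, src in enumerate(members):
            dist = nx.single_source_shortest_path_length(sub, src)
            for tgt in members[i + 1:]:
                d = dist.get(tgt)
                if d is None:
                    raise ValueError("closure is not connected in the network")
                hist[d] = hist.get(d, 0) + 1
                total += d
                n_pairs += 1
        sampled = False
        exact = True
    else:
        rng = np.random.default_rng(seed)
        m = len(members)
        iu, ju = np.triu_indices(m, k=1)
        take = min(max_pairs, iu.size)
        pick = rng.choice(iu.size, size=take, replace=False)
        ii, jj = iu[pick], ju[pick]
        # group sampled pairs by source so one BFS serves many targets
        by_src: dict[int, list[int]] = {}
        for a, b in zip(ii, jj):
            by_src.setdefault(int(a), []).append(int(b))
        for a, targets in by_src.items():
            dist = nx.single_source_shortest_path_length(sub, members[a])
            for b in targets:
                d = dist.get(members[b])
                if d is None:
                    raise ValueError("closure is not connected in the network")
                hist[d] = hist.get(d, 0) + 1
                total += d
                n_pairs += 1
        sampled = True
        exact = False
    return StepStats(
        mean_steps=total / n_pairs,
        diameter=max(hist),
        histogram=dict(sorted(hist.items())),
        n_pairs=n_pairs,
        sampled=sampled,
        seed=seed,
        diameter_exact=exact,
    )


def degree_histogram(net: TransitionNetwork | nx.Graph) -> dict[int, int]:
    """Node count per degree, including isolated (k = 0) nodes."""
    g = _graph(net)
    hist: dict[int, int] = {}
    for _, k in g.degree():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def scalefree_fit(histogram: dict[int, int]) -> DegreeFit:
    """Fit log10 P(k) ~ log10 k by least squares over degrees k >= 1.

    P(k) is the fraction of positive-degree nodes having degree k;
    the k = 0 bin is excluded (log undefined).  A Pearson r near -1
    with slope -gamma indicates a scale-free degree distribution.
    Degenerate flat distributions give r = 0 with slope 0.
    """
    pos = {k: c for k, c in histogram.items() if k >= 1 and c > 0}
    if len(pos) < 3:
        raise ValueError(
            f"insufficient degree diversity: {len(pos)} distinct degrees, need >= 3"
        )
    total = sum(pos.values())
    ks = np.array(sorted(pos))
    pk = np.array([pos[k] / total for k in ks])
    x = np.log10(ks)
    y = np.log10(pk)
    res = sps.linregress(x, y)
    r = res.rvalue
    if np.isnan(r):  # zero variance in y: flat distribution
        r = 0.0
    return DegreeFit(
        histogram=dict(pos),
        pearson_r=float(r),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(pos),
    )


def robustness_experiment(
    net: TransitionNetwork | nx.Graph,
    fractions=None,
    reps: int = 10,
    seed: int | None = None,
    max_pairs: int | None = None,
) -> pd.DataFrame:
    """Random node-removal robustness of the main closure.

    For every retain fraction and replicate, a seeded uniform node
    subset is kept, the induced subgraph is taken, and main-closure
    coverage plus step statistics of the residual main closure are
    recorded.  Columns: retain_fraction, replicate, n_nodes,
    main_closure_fraction, mean_steps, diameter.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    g = _graph(net)
    if fractions is None:
        fractions = np.round(np.arange(0.05, 1.0, 0.05), 2)
    nodes = sorted(g.nodes)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("retain fractions must be in (0, 1]")
        n_keep = max(1, int(round(f * len(nodes))))
        for rep in range(reps):
            keep = rng.choice(len(nodes), size=n_keep, replace=False)
            sub = g.subgraph([nodes[i] for i in keep])
            frac = main_closure_fraction(sub)
            mean_steps = float("nan")
            diam = 0
            if sub.number_of_nodes() >= 2:
                main = transitive_closures(sub)[0]
                if main.size >= 2:
                    st = step_stats(sub, main, max_pairs=max_pairs,
                                    seed=None if seed is None else seed + rep)
                    mean_steps = st.mean_steps
                    diam = st.diameter
            rows.append(
                (float(f), rep, sub.number_of_nodes(), frac, mean_steps, diam)
            )
    return pd.DataFrame(
        rows,
        columns=["retain_fraction", "replicate", "n_nodes",
                 "main_closure_fraction", "mean_steps", "diameter"],
    )


def transition_frequencies(
    net: TransitionNetwork,
    habitats: dict[str, str] | None = None,
) -> TransitionFrequencies:
    """Per-habitat mean direct transitions per sample.

    Mock-labeled samples are excluded.  Habitats with zero samples are
    skipped.  The within-vs-between comparison across habitats is a
    two-sided paired t-test (NaN with < 2 habitats).
    """
    g = _graph(net)
    hab = habitats if habitats is not None else net.habitat
    missing = [n for n in g.nodes if n not in hab]
    if missing:
        raise KeyError(f"nodes without habitat label: {missing[:5]}")
    nodes = [n for n in g.nodes if hab[n] != MOCK_LABEL]
    counts: dict[str, int] = {}
    for n in nodes:
        counts[hab[n]] = counts.get(hab[n], 0) + 1
    within_edges = {h: 0 for h in counts}
    between_edges = {h: 0 for h in counts}
    for a, b in g.edges:
        ha, hb = hab[a], hab[b]
        if MOCK_LABEL in (ha, hb):
            continue
        if ha == hb:
            within_edges[ha] += 1
        else:
            between_edges[ha] += 1
            between_edges[hb] += 1
    within = {h: 2.0 * within_edges[h] / counts[h] for h in counts}
    between = {h: between_edges[h] / counts[h] for h in counts}
    t_stat = p_val = float("nan")
    if len(counts) >= 2:
        order = sorted(counts)
        w = [within[h] for h in order]
        b = [between[h] for h in order]
        if not np.allclose(np.array(w) - np.array(b), (np.array(w) - np.array(b))[0]):
            res = sps.ttest_rel(w, b)
            t_stat, p_val = float(res.statistic), float(res.pvalue)
    return TransitionFrequencies(
        within=within, between=between, n_samples=counts,
        t_statistic=t_stat, p_value=p_val,
    )
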