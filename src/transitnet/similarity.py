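"""Pairwise community similarity and exhaustive top-k search.

The transition framework is agnostic to the similarity measure: any
symmetric function mapping two normalized profiles to [0, 1] (1 on
identical profiles) can drive threshold calibration and network
construction.  Two measures ship by default:

* ``braycurtis`` — 1 minus the Bray-Curtis dissimilarity, which for
  relative abundances equals the sum of element-wise minima.  Needs no
  tree and is the package default.
* ``weighted_unifrac`` — 1 minus the normalized weighted UniFrac
  distance, a phylogeny-aware measure in the same family as the
  similarity scores produced by reference-database search engines.
  Requires a rooted tree over the features.

Because the measure is pluggable, any published numeric threshold is
measure- and dataset-specific and must be recalibrated (see
:mod:`transitnet.threshold`); it is never hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import TreeNode
from skbio.diversity import beta_diversity

from .sampleset import SampleProfile, SampleSet

__all__ = [
    "SimilarityMeasure",
    "SearchHits",
    "bray_curtis_similarity",
    "phylo_similarity",
    "get_measure",
    "pairwise_similarity_matrix",
    "topk_search",
]

_SUM_TOL = 1e-6


def _check_normalized(prof: SampleProfile) -> None:
    total = sum(prof.abundances.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(
            f"profile {prof.sample_id!r} is not normalized (sum={total!r})"
        )


@dataclass(frozen=True)
class SimilarityMeasure:
    """A named symmetric similarity with scores in [0, 1].

    ``func`` takes two profiles (plus the shared feature space) and
    returns the score; ``needs_tree`` marks phylogeny-aware measures.
    """

    name: str
    func: Callable
    needs_tree: bool = False

    def __call__(self, a: SampleProfile, b: SampleProfile, **kw) -> float:
        return self.func(a, b, **kw)


@dataclass(frozen=True)
class SearchHits:
    """Ranked neighbors of one query: (neighbor_id, score), best first."""

    query_id: str
    hits: tuple[tuple[str, float], ...]
    k_requested: int

    def __post_init__(self) -> None:
        scores = [s for _, s in self.hits]
        if any(s1 < s2 for s1, s2 in zip(scores, scores[1:])):
            raise ValueError("hit scores must be non-increasing")
        if any(n == self.query_id for n, _ in self.hits):
            raise ValueError("query included in its own hits")


def bray_curtis_similarity(a: SampleProfile, b: SampleProfile) -> float:
    """Sum of element-wise minima of two relative-abundance vectors.

    Equals ``1 - Bray-Curtis dissimilarity`` when both profiles are
    normalized; 1 for identical profiles, 0 for disjoint supports.
    """
    _check_normalized(a)
    _check_normalized(b)
    shared = set(a.abundances) & set(b.abundances)
    return float(sum(min(a.abundances[f], b.abundances[f]) for f in shared))


def phylo_similarity(a: SampleProfile, b: SampleProfile, tree: TreeNode) -> float:
    """1 minus normalized weighted UniFrac between two profiles.

    Every feature with nonzero abundance in either profile must be a
    leaf of *tree*; branch lengths weight the abundance differences.
    """
    _check_normalized(a)
    _check_normalized(b)
    feats = sorted(set(a.abundances) | set(b.abundances))
    leaves = {t.name for t in tree.tips()}
    missing = [f for f in feats if f not in leaves]
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    fracs = np.array(
        [[a.abundances.get(f, 0.0) for f in feats],
         [b.abundances.get(f, 0.0) for f in feats]]
    )
    # weighted UniFrac depends only on per-sample proportions, but the
    # implementation requires integer counts: project onto a fine
    # integer grid (relative error ~1e-9)
    counts = np.round(fracs * 1e9).astype(np.int64)
    dm = beta_diversity(
        "weighted_unifrac", counts, ids=["a", "b"], taxa=feats, tree=tree,
        normalized=True, validate=True,
    )
    return float(1.0 - dm["a", "b"])


_MEASURES = {
    "braycurtis": SimilarityMeasure("braycurtis", bray_curtis_similarity),
    "weighted_unifrac": SimilarityMeasure(
        "weighted_unifrac", phylo_similarity, needs_tree=True
    ),
}


def get_measure(name: str) -> SimilarityMeasure:
    try:
        return _MEASURES[name]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; available: {sorted(_MEASURES)}"
        ) from None


def pairwise_similarity_matrix(
    sset: SampleSet,
    measure: SimilarityMeasure | str = "braycurtis",
    tree: TreeNode | None = None,
) -> pd.DataFrame:
    """Square similarity matrix over all samples (ids sorted).

    The Bray-Curtis route is vectorized through the dense abundance
    matrix; tree-based measures fall back to pairwise calls.
    """
    if isinstance(measure, str):
        measure = get_measure(measure)
    ids = sset.sample_ids
    if measure.name == "braycurtis":
        mat = sset.to_frame().to_numpy()
        # sum of minima = 1 - 0.5 * L1 distance for rows summing to 1
        sim = 1.0 - squareform(pdist(mat, metric="cityblock")) / 2.0
        np.fill_diagonal(sim, 1.0)
        sim = np.clip(sim, 0.0, 1.0)
        return pd.DataFrame(sim, index=ids, columns=ids)
    out = np.ones((len(ids), len(ids)))
    for i, si in enumerate(ids):
        for j in range(i + 1, len(ids)):
            kw = {"tree": tree} if measure.needs_tree else {}
            s = measure(sset.profiles[si], sset.profiles[ids[j]], **kw)
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=ids, columns=ids)


def topk_search(
    query_id: str,
    sset: SampleSet,
    measure: SimilarityMeasure | str = "braycurtis",
    k: int = 100,
    tree: TreeNode | None = None,
    _matrix: pd.DataFrame | None = None,
) -> SearchHits:
    """Exhaustively rank all other samples against one query.

    Ties are broken by ascending sample id so the ranking is
    deterministic across runs.  ``k`` caps the number of hits; it is
    clamped to the n-1 available neighbors.  A precomputed matrix from
    :func:`pairwise_similarity_matrix` may be passed to avoid repeated
    scoring during network construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if query_id not in sset.profiles:
        raise KeyError(f"query {query_id!r} not in sample set")
    if isinstance(measure, str):
        measure = get_measure(measure)
    others = [s for s in sset.sample_ids if s != query_id]
    if _matrix is not None:
        scored = [(s, float(_matrix.at[query_id, s])) for s in others]
    else:
        kw = {"tree": tree} if measure.needs_tree else {}
        q = sset.profiles[query_id]
        scored = [(s, measure(q, sset.profiles[s], **kw)) for s in others]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return SearchHits(query_id=query_id, hits=tuple(scored[:k]), k_requested=k)


def write_similarity_matrix(matrix: pd.DataFrame, path) -> None:
    """Export a square similarity matrix as TSV with id labels."""
    matrix.to_csv(path, sep="\t", float_format="%.12g")
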