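"""Calibration of the direct-transition similarity threshold.

Two communities are held to be linked by a "direct transition" when
their similarity is significantly high relative to the background
distribution of pairwise similarities across the whole collection.
Significance is defined by rank: a similarity is significant at level
``alpha`` when it falls in the top ``alpha`` fraction of all evaluated
pairs, so the threshold ``T_dt`` is the smallest value among the top
``ceil(alpha * N)`` of the N similarities.  No parametric null is
fitted.

For large collections the full ``n*(n-1)/2`` enumeration is quadratic;
a seeded uniform subsample of pairs estimates the same quantile and is
flagged as sampled in the calibration record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .sampleset import SampleSet
from .similarity import SimilarityMeasure, get_measure, pairwise_similarity_matrix

__all__ = [
    "ThresholdCalibration",
    "pair_count",
    "calibrate_threshold",
    "enumerate_pairwise",
    "direct_transition_prob",
    "between_habitat_pvalue",
]


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of threshold calibration.

    ``T_dt`` is the direct-transition similarity threshold; ``sampled``
    records whether the quantile was estimated from a pair subsample
    rather than the full enumeration.
    """

    T_dt: float
    alpha: float
    n_pairs_evaluated: int
    sampled: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.T_dt <= 1.0):
            raise ValueError("T_dt must be in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def pair_count(n: int) -> int:
    """Number of unordered sample pairs, n*(n-1)/2."""
    return n * (n - 1) // 2


def calibrate_threshold(similarities, alpha: float = 0.01,
                        sampled: bool = False,
                        seed: int | None = None) -> ThresholdCalibration:
    """Smallest value among the top ``ceil(alpha*N)`` similarities.

    A similarity is then "significant" (supports a direct transition)
    iff it ranks in the top ``alpha`` fraction of the N evaluated
    pairs.  Requires at least ``ceil(1/alpha)`` values so the requested
    resolution is attainable.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    vals = np.asarray(list(similarities), dtype=float)
    n = vals.size
    if n == 0:
        raise ValueError("no similarities supplied")
    if n < math.ceil(1.0 / alpha):
        raise ValueError(
            f"need >= {math.ceil(1.0 / alpha)} values for alpha={alpha}; got {n}"
        )
    m = math.ceil(alpha * n)
    top = np.partition(vals, n - m)[n - m:]
    return ThresholdCalibration(
        T_dt=float(top.min()), alpha=alpha, n_pairs_evaluated=n,
        sampled=sampled, seed=seed,
    )


def enumerate_pairwise(
    sset: SampleSet,
    measure: SimilarityMeasure | str = "braycurtis",
    max_pairs: int | None = None,
    seed: int | None = None,
    tree=None,
    habitats: dict[str, str] | None = None,
    between_only: bool = False,
) -> np.ndarray:
    """Similarities of all (or a seeded subsample of) unordered pairs.

    With ``max_pairs`` unset every ``n*(n-1)/2`` pair is scored;
    otherwise ``max_pairs`` distinct pairs are drawn uniformly without
    replacement.  ``between_only`` restricts to pairs whose samples
    carry different habitat labels (mock pairs included as labeled).
    """
    if isinstance(measure, str):
        measure = get_measure(measure)
    ids = sset.sample_ids
    n = len(ids)
    mat = pairwise_similarity_matrix(sset, measure, tree=tree).to_numpy()
    iu, ju = np.triu_indices(n, k=1)
    if between_only:
        hab = habitats or sset.habitat
        labels = np.array([hab[s] for s in ids])
        keep = labels[iu] != labels[ju]
        iu, ju = iu[keep], ju[keep]
    scores = mat[iu, ju]
    total = scores.size
    if max_pairs is None or max_pairs >= total:
        if max_pairs is not None and max_pairs > total:
            warnings.warn(
                f"max_pairs={max_pairs} exceeds the {total} available pairs; "
                "using all pairs", stacklevel=2,
            )
        return scores
    rng = np.random.default_rng(seed)
    pick = rng.choice(total, size=max_pairs, replace=False)
    return scores[pick]


def direct_transition_prob(a, b, measure, T_dt: float, tree=None) -> float:
    """Probability-weight of a direct transition between two profiles.

    Returns ``sim(a, b)`` when the similarity meets the threshold
    (inclusive) and 0 otherwise: above-threshold similarity is read as
    the transition probability itself.
    """
    if isinstance(measure, str):
        measure = get_measure(measure)
    kw = {"tree": tree} if measure.needs_tree else {}
    s = measure(a, b, **kw)
    return s if s >= T_dt else 0.0


def between_habitat_pvalue(T_dt: float, between_scores) -> float:
    """Upper-tail permutation p-value of the threshold among
    between-habitat similarities: ``(#{s >= T_dt} + 1) / (N + 1)``.

    The add-one convention keeps the estimate away from zero at finite
    N.  A small p says the threshold is rarely reached by pairs drawn
    from different habitats.
    """
    scores = np.asarray(list(between_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("between_scores is empty")
    exceed = int(np.count_nonzero(scores >= T_dt))
    return (exceed + 1) / (scores.size + 1)
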