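"""Habitat prediction from ranked network neighbors.

A sample's habitat is inferred from its top n = 10 network neighbors,
ranked by edge similarity.  With neighbor similarities s_1 >= ... >=
s_n, habitat h_k receives the rank-and-similarity weight

    P(a in h_k) = sum_{j in h_k} (n - j + 1) * s_j
                  / sum_{i=1..n} (n - i + 1) * s_i

so the nearest neighbors dominate both through their rank (n - j + 1)
and their similarity.  The argmax habitat is the prediction.  The
classifier is evaluated by leave-one-out cross-validation: each sample
is predicted purely from its neighbors' labels (self-edges do not
exist, so its own label never contributes).

The habitat-connectivity recursion extends the measured within-habitat
assignment rate p to the chance that n habitats end up linked in one
network: connecting two habitats succeeds with 1 - p, and each further
habitat joins the connected block of n - 1 habitats unless all n - 1
potential links fail, giving

    p_conn(2) = 1 - p
    p_conn(n) = p_conn(n - 1) * (1 - p^(n - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import TransitionNetwork
from .sampleset import MOCK_LABEL

__all__ = [
    "PredictionResult",
    "LoocvReport",
    "predict_habitat",
    "loocv_evaluate",
    "habitat_connectivity_prob",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    probabilities: dict[str, float]
    predicted: str | None
    n_neighbors_used: int
    abstained: bool = False


@dataclass
class LoocvReport:
    """Per-habitat and overall leave-one-out accuracy plus mismatches."""

    per_habitat: pd.DataFrame  # index habitat; columns n, n_correct, accuracy_pct
    overall_accuracy_pct: float
    mismatch_matrix: pd.DataFrame  # true x predicted counts
    n_abstained: int
    n_samples: int
    n_mismatches: int


def predict_habitat(
    sample_id: str,
    net: TransitionNetwork,
    habitats: dict[str, str] | None = None,
    n: int = 10,
) -> PredictionResult:
    """Rank-weighted neighbor vote for one sample's habitat.

    Mock-labeled neighbors are dropped before ranking; when fewer than
    *n* neighbors exist, the weights use the actual count so they stay
    positive.  An isolated sample abstains.  Probability ties are
    broken by habitat name ascending.
    """
    hab = habitats if habitats is not None else net.habitat
    nbrs = [(s, sim) for s, sim in net.neighbors_ranked(sample_id)
            if hab.get(s) != MOCK_LABEL][:n]
    if not nbrs:
        return PredictionResult(
            sample_id=sample_id, probabilities={}, predicted=None,
            n_neighbors_used=0, abstained=True,
        )
    m = len(nbrs)
    weights: dict[str, float] = {}
    denom = 0.0
    for j, (nbr, sim) in enumerate(nbrs, start=1):
        w = (m - j + 1) * sim
        weights[hab[nbr]] = weights.get(hab[nbr], 0.0) + w
        denom += w
    probs = {h: w / denom for h, w in weights.items()}
    predicted = min(probs, key=lambda h: (-probs[h], h))
    return PredictionResult(
        sample_id=sample_id, probabilities=probs, predicted=predicted,
        n_neighbors_used=m,
    )


def loocv_evaluate(
    net: TransitionNetwork,
    habitats: dict[str, str] | None = None,
    n: int = 10,
) -> LoocvReport:
    """Leave-one-out evaluation of the neighbor classifier.

    Every non-mock sample is predicted from its neighbors; abstentions
    (isolated samples) count as incorrect and are also reported
    separately.  The mismatch matrix counts true x predicted habitat
    pairs, with abstentions in an ``unassigned`` column so each row
    sums to the habitat's sample count.
    """
    hab = habitats if habitats is not None else net.habitat
    samples = [s for s in sorted(net.graph.nodes) if hab[s] != MOCK_LABEL]
    labels = sorted({hab[s] for s in samples})
    # abstentions land in a dedicated column so row sums equal habitat sizes
    mismatch = pd.DataFrame(0, index=labels, columns=labels + ["unassigned"],
                            dtype=int)
    per = {h: [0, 0] for h in labels}  # habitat -> [n, n_correct]
    n_abstained = 0
    for s in samples:
        truth = hab[s]
        per[truth][0] += 1
        res = predict_habitat(s, net, habitats=hab, n=n)
        if res.abstained:
            n_abstained += 1
            mismatch.loc[truth, "unassigned"] += 1
            continue
        mismatch.loc[truth, res.predicted] += 1
        if res.predicted == truth:
            per[truth][1] += 1
    table = pd.DataFrame(
        {
            "n": {h: per[h][0] for h in labels},
            "n_correct": {h: per[h][1] for h in labels},
        }
    )
    table["accuracy_pct"] = 100.0 * table["n_correct"] / table["n"].where(table["n"] > 0)
    total = int(table["n"].sum())
    correct = int(table["n_correct"].sum())
    overall = 100.0 * correct / total if total else float("nan")
    return LoocvReport(
        per_habitat=table,
        overall_accuracy_pct=overall,
        mismatch_matrix=mismatch,
        n_abstained=n_abstained,
        n_samples=total,
        n_mismatches=total - correct,
    )


def habitat_connectivity_prob(n_habitats: int, p_within: float = 0.8928) -> float:
    """Chance that n habitats are all linked despite habitat-faithful
    structure.

    ``p_within`` is the probability a sample's strongest links stay in
    its own habitat (normally the leave-one-out within-habitat
    assignment rate).  The recursion multiplies the two-habitat link
    chance 1 - p_within by, for each added habitat, the chance that not
    all of its n - 1 potential cross-habitat links fail.
    """
    if n_habitats < 2:
        raise ValueError("n_habitats must be >= 2")
    if not (0.0 < p_within < 1.0):
        raise ValueError("p_within must be in (0, 1)")
    p = 1.0 - p_within
    for m in range(3, n_habitats + 1):
        p *= 1.0 - p_within ** (m - 1)
    return p
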