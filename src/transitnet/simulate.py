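"""Synthetic habitat-structured communities and transition chains.

The generator emulates the statistical shape the transition framework
relies on: samples cluster by habitat, so within-habitat similarity
stochastically exceeds between-habitat similarity.  Each habitat gets
a base composition over a feature block that shares a configurable
fraction of features with other habitats, and samples are drawn around
the base with Dirichlet noise whose concentration sets how tight the
habitat cluster is.  Optionally, chains of intermediate profiles are
planted between chosen habitat pairs so that consecutive similarities
stay above a bridge threshold — the raw material for closures that
merge across habitats.

Transition chains are built by convex interpolation of compositions:
between two normalized profiles p and q the interpolates are
(1 - t) p + t q, which are themselves normalized, and the number of
steps is grown until every consecutive similarity clears the
requested threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sampleset import MOCK_LABEL, SampleProfile, SampleSet
from .similarity import SimilarityMeasure, get_measure

__all__ = [
    "GeneratorConfig",
    "generate_habitat_dataset",
    "generate_transition_chain",
    "random_feature_tree",
]

_ZERO_EPS = 1e-12


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic habitat dataset.

    Parameters
    ----------
    n_habitats, samples_per_habitat, n_features : int
        Dataset shape.  Habitats are labeled ``H1 .. Hn``.
    concentration : float
        Dirichlet concentration around each habitat base; higher means
        tighter within-habitat similarity (the infinite limit makes all
        samples of a habitat identical).
    base_overlap : float
        Fraction of the feature space shared among all habitat bases;
        0 gives disjoint supports, hence zero between-habitat
        Bray-Curtis similarity.
    habitat_adjacency : tuple of (str, str)
        Habitat pairs to join with planted transition chains whose
        consecutive similarities stay >= ``bridge_min_similarity``.
    n_mock : int
        Extra mock-labeled control samples drawn from a uniform base.
    """

    n_habitats: int = 3
    samples_per_habitat: int = 20
    n_features: int = 100
    concentration: float = 300.0
    base_overlap: float = 0.3
    habitat_adjacency: tuple[tuple[str, str], ...] = ()
    bridge_min_similarity: float = 0.9
    n_mock: int = 0
    total_count_range: tuple[int, int] = (5_000, 50_000)
    map_rate_range: tuple[float, float] = (0.85, 0.99)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_habitats, self.samples_per_habitat, self.n_features) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.base_overlap <= 1.0):
            raise ValueError("base_overlap must be in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def _habitat_supports(cfg: GeneratorConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    """Feature space plus a boolean support mask per habitat."""
    f = cfg.n_features
    n_shared = int(round(cfg.base_overlap * f))
    n_private = (f - n_shared) // cfg.n_habitats
    if cfg.base_overlap < 1.0 and n_private < 1:
        raise ValueError(
            f"infeasible overlap: {f} features cannot give each of "
            f"{cfg.n_habitats} habitats a private block at overlap "
            f"{cfg.base_overlap}"
        )
    features = [f"F{i:04d}" for i in range(f)]
    supports = {}
    for h in range(cfg.n_habitats):
        mask = np.zeros(f, dtype=bool)
        mask[:n_shared] = True
        lo = n_shared + h * n_private
        mask[lo:lo + n_private] = True
        supports[f"H{h + 1}"] = mask
    return features, supports


def _profile_from_vector(
    sid: str, vec: np.ndarray, features: list[str], total: int, rate: float
) -> SampleProfile:
    vec = np.asarray(vec, dtype=float)
    vec = vec / vec.sum()
    ab = {features[i]: float(v) for i, v in enumerate(vec) if v > _ZERO_EPS}
    # re-normalize after dropping numerically-zero entries
    s = sum(ab.values())
    ab = {k: v / s for k, v in ab.items()}
    return SampleProfile(sample_id=sid, abundances=ab,
                         total_count=total, map_rate=rate)


def generate_habitat_dataset(cfg: GeneratorConfig) -> SampleSet:
    """Draw a habitat-labeled sample set under the configured conditions.

    Per habitat a base composition is drawn over its feature support
    and samples follow Dirichlet(concentration * base).  Planted
    chains for each adjacency pair run from the first sample of one
    habitat to the first of the other; chain interiors become bridge
    samples labeled with the nearer habitat.  Fully reproducible from
    the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    features, supports = _habitat_supports(cfg)
    bases: dict[str, np.ndarray] = {}
    profiles: dict[str, SampleProfile] = {}
    habitat: dict[str, str] = {}

    def meta():
        total = int(rng.integers(*cfg.total_count_range))
        rate = float(rng.uniform(*cfg.map_rate_range))
        return total, rate

    for h, mask in supports.items():
        base = np.zeros(cfg.n_features)
        base[mask] = rng.dirichlet(np.ones(int(mask.sum())))
        bases[h] = base
        alpha = cfg.concentration * base[mask]
        # Dirichlet needs strictly positive alphas; the support mask
        # guarantees it
        for i in range(cfg.samples_per_habitat):
            vec = np.zeros(cfg.n_features)
            vec[mask] = rng.dirichlet(alpha)
            sid = f"{h}_s{i:03d}"
            total, rate = meta()
            profiles[sid] = _profile_from_vector(sid, vec, features, total, rate)
            habitat[sid] = h

    for ha, hb in cfg.habitat_adjacency:
        for h in (ha, hb):
            if h not in supports:
                raise ValueError(f"adjacency names unknown habitat {h!r}")
        start = profiles[f"{ha}_s000"]
        end = profiles[f"{hb}_s000"]
        chain = generate_transition_chain(
            start, end, T_dt=cfg.bridge_min_similarity,
            feature_space=features, max_steps=10_000,
        )
        interior = chain[1:-1]
        for t, prof in enumerate(interior):
            sid = f"bridge_{ha}_{hb}_{t:03d}"
            total, rate = meta()
            profiles[sid] = SampleProfile(
                sample_id=sid, abundances=prof.abundances,
                total_count=total, map_rate=rate,
            )
            habitat[sid] = ha if t < len(interior) / 2 else hb

    for i in range(cfg.n_mock):
        vec = rng.dirichlet(np.ones(cfg.n_features))
        sid = f"mock_s{i:03d}"
        total, rate = meta()
        profiles[sid] = _profile_from_vector(sid, vec, features, total, rate)
        habitat[sid] = MOCK_LABEL

    return SampleSet(profiles=profiles, habitat=habitat, feature_space=features)


def generate_transition_chain(
    start: SampleProfile,
    end: SampleProfile,
    T_dt: float,
    measure: SimilarityMeasure | str = "braycurtis",
    max_steps: int = 1000,
    feature_space: list[str] | None = None,
    tree=None,
) -> list[SampleProfile]:
    """Chain of profiles from *start* to *end* with every consecutive
    similarity >= ``T_dt``.

    Convex interpolation of compositions; the step count starts at the
    closed-form bound for the default measure (consecutive Bray-Curtis
    similarity of an m-step linear chain is 1 - |p - q|_1 / (2 m)) and
    doubles until every link verifies, erroring beyond ``max_steps``.
    Endpoints are included; a 1-step chain means the pair is already
    directly linked.
    """
    if isinstance(measure, str):
        measure = get_measure(measure)
    if start.abundances == end.abundances:
        raise ValueError("start and end profiles are identical")
    feats = feature_space or sorted(set(start.abundances) | set(end.abundances))
    p = start.vector(feats)
    q = end.vector(feats)
    l1 = float(np.abs(p - q).sum())
    if T_dt <= 0:
        m = 1
    else:
        m = max(1, math.ceil(l1 / max(2.0 * (1.0 - T_dt), _ZERO_EPS)))
    while m <= max_steps:
        vecs = [(1 - t) * p + t * q for t in np.linspace(0.0, 1.0, m + 1)]
        chain = [start]
        for i, v in enumerate(vecs[1:-1], start=1):
            chain.append(
                _profile_from_vector(
                    f"{start.sample_id}->{end.sample_id}#{i}", v, feats,
                    total=start.total_count, rate=start.map_rate or 1.0,
                )
            )
        chain.append(end)
        kw = {"tree": tree} if measure.needs_tree else {}
        if all(
            measure(a, b, **kw) >= T_dt for a, b in zip(chain, chain[1:])
        ):
            return chain
        m *= 2
    raise ValueError(
        f"no chain with consecutive similarity >= {T_dt} within "
        f"{max_steps} steps"
    )


def random_feature_tree(feature_ids, seed: int | None = None) -> str:
    """Random bifurcating newick tree over the features (unit-ish branch
    lengths), for exercising phylogeny-aware similarity."""
    rng = np.random.default_rng(seed)
    nodes = [f"{fid}:{rng.uniform(0.5, 1.5):.4f}" for fid in feature_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 0.8):.4f}")
    return f"{nodes[0][:nodes[0].rfind(':')]};" if len(feature_ids) > 1 else f"({nodes[0]});"
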