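import numpy as np
import pytest

from transitnet import GeneratorConfig, SampleProfile, SampleSet, generate_habitat_dataset


def make_profile(sid, fracs, features=None, total=1000, rate=0.95):
    """Profile from a raw vector (normalized here for convenience)."""
    fracs = np.asarray(fracs, dtype=float)
    fracs = fracs / fracs.sum()
    features = features or [f"F{i}" for i in range(len(fracs))]
    ab = {f: float(v) for f, v in zip(features, fracs) if v > 0}
    return SampleProfile(sample_id=sid, abundances=ab, total_count=total,
                         map_rate=rate)


def make_set(vectors, habitats=None, features=None, totals=None, rates=None):
    """SampleSet from {sid: vector}; habitats default to one label."""
    n_feat = max(len(v) for v in vectors.values())
    features = features or [f"F{i}" for i in range(n_feat)]
    profiles = {}
    for sid, vec in vectors.items():
        profiles[sid] = make_profile(
            sid, vec, features[: len(vec)],
            total=(totals or {}).get(sid, 1000),
            rate=(rates or {}).get(sid, 0.95),
        )
    habitats = habitats or {sid: "A" for sid in vectors}
    return SampleSet(profiles=profiles, habitat=dict(habitats),
                     feature_space=features)


@pytest.fixture
def random_set():
    """20 samples over 12 features, two habitats, seeded."""
    rng = np.random.default_rng(42)
    vectors = {f"s{i:02d}": rng.dirichlet(np.ones(12) * 2) for i in range(20)}
    habitats = {sid: ("A" if i < 10 else "B")
                for i, sid in enumerate(vectors)}
    return make_set(vectors, habitats)


@pytest.fixture(scope="session")
def habitat_dataset():
    """Default-condition synthetic dataset: 3 habitats x 20 samples."""
    return generate_habitat_dataset(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def chained_dataset():
    """3 habitats with planted H1-H2 and H2-H3 transition chains."""
    cfg = GeneratorConfig(
        seed=11, habitat_adjacency=(("H1", "H2"), ("H2", "H3")),
        bridge_min_similarity=0.75,
    )
    return generate_habitat_dataset(cfg)
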