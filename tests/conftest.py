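import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpihash import BinaryFingerprint, InteractionDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_fingerprint(entity_id, dimension, active):
    return BinaryFingerprint(entity_id, dimension, tuple(sorted(active)))


@pytest.fixture
def tiny_dataset():
    """4 compounds x 3 proteins, D=6, D'=5, handcrafted labels."""
    compounds = {
        f"c{i}": make_fingerprint(f"c{i}", 6, active)
        for i, active in enumerate([(0, 2), (1, 3, 5), (0, 4), (2,)])
    }
    proteins = {
        f"p{j}": make_fingerprint(f"p{j}", 5, active)
        for j, active in enumerate([(1,), (0, 3), (2, 4)])
    }
    pairs = [
        ("c0", "p0", 1),
        ("c0", "p1", -1),
        ("c1", "p0", 1),
        ("c1", "p2", -1),
        ("c2", "p1", 1),
        ("c2", "p2", -1),
        ("c3", "p0", -1),
        ("c3", "p2", 1),
    ]
    return InteractionDataset(compounds=compounds, proteins=proteins, pairs=pairs)


@pytest.fixture
def random_sets():
    """Deterministic pairs of random subsets of a small universe."""
    rng = np.random.default_rng(42)

    def draw(m=200, n_pairs=1, min_size=3, max_size=40):
        out = []
        for _ in range(n_pairs):
            size1 = int(rng.integers(min_size, max_size))
            size2 = int(rng.integers(min_size, max_size))
            s1 = set(rng.choice(m, size=size1, replace=False).tolist())
            s2 = set(rng.choice(m, size=size2, replace=False).tolist())
            # overlap part of s1 into s2 so Jaccard spans (0, 1)
            take = int(rng.integers(0, min(len(s1), len(s2)) + 1))
            s2 = set(list(s2)[take:]) | set(list(s1)[:take])
            out.append((s1, s2))
        return out if len(out) > 1 else out[0]

    return draw
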