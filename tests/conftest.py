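from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psermkit.reads import merge_replicates

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_table():
    """Two rounds, two replicates, three clones of length 2 (WT = 'AY')."""
    tallies = {
        ("R1", 1): Counter({"AY": 90, "AA": 6, "CY": 4}),
        ("R1", 2): Counter({"AY": 88, "AA": 8, "CY": 4}),
        ("R2", 1): Counter({"AY": 85, "AA": 12, "CY": 3}),
        ("R2", 2): Counter({"AY": 86, "AA": 11, "CY": 3}),
    }
    return merge_replicates(tallies, ["R1", "R2"], wt_string="AY")


def random_tallies(rng, n_clones, length, rounds, replicates=2, max_count=50):
    """Random per-(round, replicate) tallies over a shared clone pool."""
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    clones = list({"".join(rng.choice(aa, length)) for _ in range(n_clones)})
    tallies = {}
    for r in rounds:
        for k in range(1, replicates + 1):
            counts = {
                c: int(rng.integers(0, max_count)) for c in clones
            }
            tallies[(r, k)] = Counter({c: n for c, n in counts.items() if n > 0})
    return clones, tallies
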