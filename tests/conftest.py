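import itertools

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def all_signed_arrangements(n):
    """Every signed arrangement of n blocks, as signed tuples (2^n * n!)."""
    out = []
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            out.append(tuple(p * s for p, s in zip(perm, signs)))
    return out


@pytest.fixture(scope="session")
def distances_by_n():
    """Exact distance from identity to every state, for n = 1..4."""
    from dimsum.search import all_min_distances

    return {n: all_min_distances(n) for n in (1, 2, 3, 4)}
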