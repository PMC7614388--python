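import itertools

import pytest
from hypothesis import settings

from insptools.algebra import PhosphoInositol

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def all_states():
    """All 64 phosphorylation states of the myo-inositol ring (no PP)."""
    states = []
    for n in range(7):
        for combo in itertools.combinations(range(1, 7), n):
            states.append(PhosphoInositol(frozenset(combo)))
    return states


@pytest.fixture(scope="session")
def ideal_chair():
    from insptools.geometry import build_ideal_chair

    return build_ideal_chair()
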