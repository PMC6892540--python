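import numpy as np
import pytest

from chronograft.simulate import simulate_bd_tree


@pytest.fixture(scope="session")
def yule_trees():
    """A reusable batch of small pure-birth trees (deterministic)."""
    rng = np.random.default_rng(42)
    return [simulate_bd_tree(0.3, 0.0, 8, rng=rng) for _ in range(50)]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
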