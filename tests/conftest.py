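import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ohnolog import canonical_scenarios


@pytest.fixture(scope="session")
def small_scenarios():
    """The four canonical scenarios scaled to 40 families for fast tests."""
    return canonical_scenarios(n_families=40)


@pytest.fixture(scope="session")
def noise_free_scenarios():
    return canonical_scenarios(n_families=30, q=0.0, loss_prob=0.0)
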