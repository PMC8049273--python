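import numpy as np
import pytest

from sctgeno.panel import default_panel
from sctgeno.read_processing import AmpliconAligner


@pytest.fixture(scope="session")
def panel():
    """Bundled 49-amplicon panel with a seeded synthetic reference."""
    return default_panel(reference_seed=20240915)


@pytest.fixture(scope="session")
def aligner(panel):
    return AmpliconAligner(panel)


@pytest.fixture
def rng():
    return np.random.default_rng(77)
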