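import numpy as np
import pytest

from cnvburden.config import AnalysisConfig
from cnvburden.synthetic import make_layout, make_probe_design


@pytest.fixture(scope="session")
def tiny_layout():
    """2 x 8 Mbp genome with 4 hotspots of 300-500 kbp."""
    return make_layout(
        seed=7, n_chromosomes=2, chromosome_length_bp=8_000_000,
        n_hotspots=4, hotspot_size_range=(300_000, 500_000),
    )


@pytest.fixture(scope="session")
def tiny_design(tiny_layout):
    return make_probe_design(tiny_layout, seed=7)


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_927)
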