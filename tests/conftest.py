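import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from screenseq.panel import plate_layout
from screenseq.simulate import synthetic_barcodes, synthetic_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_panel():
    """4 assays (2 UMI, 2 non-UMI) over 4 genes."""
    return synthetic_panel(n_assays=4, n_genes=4, seed=3)


@pytest.fixture(scope="session")
def control_design():
    """24-well all-control plate with barcodes attached."""
    design = plate_layout([], [], n_untreated=12, n_vehicle=12)
    return design.attach_barcodes(synthetic_barcodes(seed=5))


@pytest.fixture(scope="session")
def barcodes():
    return synthetic_barcodes(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
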