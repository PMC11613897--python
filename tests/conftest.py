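import pytest

from brcascreen.config import SimConfig
from brcascreen.cohort import generate_cohort
from brcascreen.model import build_analysis_frame


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort, fixed seed, shared across tests."""
    return generate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    return build_analysis_frame(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Quarter-size cohort for cheaper structural checks."""
    cfg = SimConfig(seed=7).replace(
        n_women=6000,
        gene_carrier_counts={"BRCA1": 17, "BRCA2": 21, "PALB2": 9,
                             "ATM": 22, "CHEK2": 27},
    )
    return generate_cohort(cfg)
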