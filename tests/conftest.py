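import pytest

import lctrs
from lctrs import datasets


@pytest.fixture(scope="session")
def paridis():
    return datasets.paridis_panel()


@pytest.fixture(scope="session")
def strt(paridis):
    return lctrs.compute_strt(paridis)


@pytest.fixture(scope="session")
def pair(strt):
    return lctrs.make_reference_pair(strt, "Chonglou saponin VII", "Chonglou saponin I")


@pytest.fixture(scope="session")
def rr_model():
    return datasets.paridis_rr_model()


@pytest.fixture(scope="session")
def dead_times():
    """Nominal hold-up time per column from geometry (0.65·π·r²·L / F)."""
    info = datasets.paridis_column_info()
    return {c: (2.70 if "250" in g else 1.62) for c, g in info.geometry.items()}
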