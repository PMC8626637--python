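import pytest

from fetalkp.datasets import IN_VIVO_PGP_ABUNDANCE, published_efflux_table
from fetalkp.examples import example_parameter_set, example_regimen


@pytest.fixture(scope="session")
def drv_params():
    """DRV-like term parameter set (K_p,uu = 0.16 by construction)."""
    return example_parameter_set("DRV")


@pytest.fixture(scope="session")
def drv_regimen():
    return example_regimen("DRV")


@pytest.fixture(scope="session")
def efflux_table():
    return published_efflux_table()


@pytest.fixture(scope="session")
def in_vivo_abundance():
    return IN_VIVO_PGP_ABUNDANCE
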