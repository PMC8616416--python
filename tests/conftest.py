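import numpy as np
import pytest

from fluordepth import preset_amplitudes, preset_triple


@pytest.fixture(scope="session")
def dermis():
    """Human-dermis spectral triple with its uniform-profile PS amplitudes."""
    return preset_triple("dermis_table1"), preset_amplitudes("dermis_table1")


@pytest.fixture(scope="session")
def dermis_m0():
    """Integrated amplitudes M0 for total-amount-conserving exponential profiles."""
    return preset_amplitudes("dermis_table1", conserve_total=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
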