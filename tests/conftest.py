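import numpy as np
import pytest

from trapquench import core, synth


@pytest.fixture
def cfg():
    return core.DEFAULT_CONFIG


@pytest.fixture
def tr():
    return core.get_preset("texas_red")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def inst():
    return synth.InstrumentModel()


@pytest.fixture
def inst_no_irf():
    # delta-function IRF and no background: clean exponential statistics
    return synth.InstrumentModel(irf_fwhm_ps=0.0, background_per_bin=0.0)
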