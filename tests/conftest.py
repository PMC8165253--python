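import numpy as np
import pytest

from pamesoscope import experiments, synthetic


@pytest.fixture(scope="session")
def default_sensor():
    """Packaged 23 MHz ringing sensor at the default 125 MHz sampling rate."""
    return synthetic.make_default_sensor()


@pytest.fixture(scope="session")
def wire_result():
    """Scaled-down wire-phantom resolution experiment (simulate -> UBP ->
    envelope -> Gaussian fits), shared by the end-to-end tests."""
    return experiments.wire_resolution_experiment(seed=1)


@pytest.fixture(scope="session")
def vessel_result():
    """Dual-wavelength artery/vein study on the synthetic vessel phantom."""
    return experiments.vessel_dualwave_experiment(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
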