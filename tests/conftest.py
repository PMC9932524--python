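import numpy as np
import pytest

from flimoct import config
from flimoct.deconv import LaguerreDeconvolver, laguerre_basis


@pytest.fixture(scope="session")
def irf():
    return config.default_irf_samples()


@pytest.fixture(scope="session")
def window_time():
    return np.arange(config.WINDOW_SAMPLES) * config.DT_NS


@pytest.fixture(scope="session")
def default_basis():
    return laguerre_basis(config.WINDOW_SAMPLES, config.LAGUERRE_ORDER,
                          config.LAGUERRE_ALPHA[0])


@pytest.fixture(scope="session")
def engine(irf, default_basis):
    return LaguerreDeconvolver(irf, default_basis)


@pytest.fixture(scope="session")
def mono_decay(irf, window_time):
    """Factory: window waveform of a mono-exponential convolved with the IRF."""
    n = config.WINDOW_SAMPLES

    def make(tau, amplitude=1.0):
        decay = amplitude * np.exp(-window_time / tau) / tau
        return np.convolve(irf, decay)[:n]

    return make


@pytest.fixture(scope="session")
def week4_stack_and_phantom():
    """One default week-4 phantom run through the full FLIm pipeline."""
    import flimoct as F

    ph = F.build_phantom(F.preset_spec("week4_invitro", seed=1))
    scan = F.render_flim_scan(ph)
    stack = F.snr_filter(F.process_scan(scan))
    return stack, ph
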