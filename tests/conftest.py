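import numpy as np
import pytest
from scipy import signal

from optoipsc import (KernelParams, SessionConfig, ipsc_kernel,
                      simulate_vc_session)

FS = 20000.0


@pytest.fixture(scope="session")
def kernel():
    return KernelParams()


@pytest.fixture(scope="session")
def short_session():
    """10-min default-parameter session with ground truth (shared, read-only)."""
    return simulate_vc_session(SessionConfig(duration=10.0, seed=42))


@pytest.fixture
def noisy_trace():
    """One 5-s sweep of band-limited 5-pA noise plus an injection helper."""
    rng = np.random.default_rng(7)
    sos = signal.bessel(4, 4000.0, fs=FS, output="sos")
    data = signal.sosfilt(sos, rng.normal(0.0, 5.0, int(5 * FS)))
    data *= 5.0 / data[: int(0.75 * FS)].std()

    def inject(latency_ms, amplitude, kp=None):
        kp = kp or KernelParams()
        klen = int(10 * kp.tau_decay * FS / 1000)
        t = np.arange(klen) / FS * 1000.0
        idx = int(round((1.0 + latency_ms / 1000.0) * FS))
        data[idx: idx + klen] += ipsc_kernel(t, kp, amplitude)
        return data

    return data, inject
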