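import numpy as np
import pytest

from smanet.synthetic import SynthSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixture_recording():
    """Three-channel ictal mixture: low rhythms + broadband EMG, known parts."""
    spec = SynthSpec(
        channels=("Fp1", "Fp2", "Fz"),
        duration_s=20.0,
        seed=3,
        rhythms=((8.0, 30.0), (11.0, 20.0)),
        emg_band=(40.0, 150.0),
        emg_rms=25.0,
        kappa=0.5,
    )
    return generate_recording(spec)


@pytest.fixture(scope="session")
def rhythm_only_recording():
    """Single channel of a pure narrowband 8 Hz rhythm (negligible EMG)."""
    spec = SynthSpec(
        channels=("Fz",),
        duration_s=10.0,
        seed=1,
        rhythms=((8.0, 30.0),),
        emg_rms=1e-12,
    )
    return generate_recording(spec)
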