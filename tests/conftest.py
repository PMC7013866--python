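import numpy as np
import pytest

from henvox.audio_io import AudioClip
from henvox.config import PipelineConfig
from henvox.synth import build_corpus, load_class_specs

RATE = 16_000


def tone(freq_hz: float, duration_s: float = 1.0, rate: int = RATE,
         amplitude: float = 0.8) -> AudioClip:
    t = np.arange(int(duration_s * rate)) / rate
    return AudioClip(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                     rate=rate, source_id=f"tone{freq_hz:g}")


@pytest.fixture(scope="session")
def class_specs():
    return load_class_specs()


@pytest.fixture(scope="session")
def small_corpus():
    """Shared 4-class corpus (20 calls/class, 15 dB SNR) for pipeline tests."""
    return build_corpus(n_per_class=20, snr_db=15.0, seed=11)


@pytest.fixture()
def cfg():
    c = PipelineConfig()
    c.seed = 11
    return c
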