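import numpy as np
import pytest

from pausekit.audio_io import TARGET_RATE, AudioSignal
from pausekit.synth import SpeechGenConfig, generate_corpus
from pausekit.vad import GaussianMixture1D, VadModel, fit_default_model


def tone(freq: float, duration: float, sr: int = TARGET_RATE, amplitude: float = 0.5) -> AudioSignal:
    t = np.arange(int(duration * sr)) / sr
    return AudioSignal(amplitude * np.sin(2 * np.pi * freq * t), sr)


def random_mixture(rng: np.random.Generator) -> GaussianMixture1D:
    w1 = rng.uniform(0.05, 0.95)
    return GaussianMixture1D(
        weights=np.array([w1, 1.0 - w1]),
        means=rng.uniform(-80.0, 20.0, 2),
        stds=rng.uniform(0.5, 15.0, 2),
    )


def random_model(rng: np.random.Generator) -> VadModel:
    K = rng.uniform(0.1, 1.0, 6)
    K /= K.sum()
    return VadModel(
        silent=[random_mixture(rng) for _ in range(6)],
        voiced=[random_mixture(rng) for _ in range(6)],
        K=K,
        Tm=rng.uniform(-90.0, -10.0),
        T_tau=rng.uniform(0.0, 2.0),
        T_a=rng.uniform(0.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_corpus():
    """4+4 subjects, 30 s recordings, strong pause contrast; shared across tests."""
    cfg = SpeechGenConfig(n_subjects_per_group=4, duration=30.0, seed=7)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_vad_model(small_corpus):
    return fit_default_model(small_corpus.signals[:4])
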