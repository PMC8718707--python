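import numpy as np
import pytest

from memae.autoencoder import ArchConfig, ECGBeat
from memae.synthetic import default_specs, generate_dataset


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture
def small_arch():
    """A light architecture for unit tests (latent width 8, total stride 16)."""
    return ArchConfig(channels=(4, 4, 8, 8))


@pytest.fixture(scope="session")
def tiny_dataset(specs):
    """24 beats per class of the two easy morphologies, window 64."""
    return generate_dataset(
        {k: specs[k] for k in ("paced", "routine")}, 24, t_len=64, seed=11)


def make_beats(n, t_len=64, label=None, seed=0):
    """Unlabelled random beats for shape/plumbing tests."""
    rng = np.random.default_rng(seed)
    return [ECGBeat(samples=rng.normal(size=(1, t_len)), label=label,
                    source_id=f"rand-{i}") for i in range(n)]
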