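import numpy as np
import pytest

from qeegconn.signal_io import EpochSet, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, rate=250.0, labels=None, **meta):
    samples = np.asarray(samples, dtype=float)
    if labels is None:
        labels = [f"C{2 * k + 3}" for k in range(samples.shape[0])]
    return Recording(samples=samples, rate=rate, labels=labels, meta=meta)


def make_epochs(samples, rate=250.0, labels=None, n_epochs=1):
    """Wrap a channels x timepoints array into an EpochSet, split evenly."""
    samples = np.asarray(samples, dtype=float)
    if labels is None:
        labels = ["C3", "C4", "P3", "P4", "F3", "F4"][: samples.shape[0]]
    length = samples.shape[1] // n_epochs
    epochs = [samples[:, k * length:(k + 1) * length] for k in range(n_epochs)]
    return EpochSet(epochs=epochs, epoch_length_s=length / rate,
                    kept_mask=np.ones(n_epochs, dtype=bool),
                    rate=rate, labels=list(labels))


@pytest.fixture
def epoch_factory():
    return make_epochs


@pytest.fixture
def recording_factory():
    return make_recording
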