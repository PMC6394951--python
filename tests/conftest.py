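import numpy as np
import pytest

from plinet.epochs import EpochSet
from plinet.synthdata import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def white_noise_epochs(rng):
    """95 epochs of 5-channel white noise at 1 kHz, 2048 samples."""
    return EpochSet(rng.standard_normal((95, 5, 2048)), fs=1000.0,
                    labels=[f"R{i}" for i in range(5)])


def make_sim(planted=None, *, n_rois=3, epochs=30, band=(8.0, 12.0),
             noise_sd=0.0, seed=1, fs=1000.0, epoch_ms=2048.0):
    """One-condition oscillator config with optional planted edges."""
    return SimConfig(
        n_subjects=1, n_rois=n_rois, conditions=("c",),
        epochs_per_condition=epochs, epoch_ms=epoch_ms, fs=fs,
        bands=(band,),
        planted_edges={"c": {0: list(planted)}} if planted else {},
        noise_sd=noise_sd, seed=seed,
    )
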