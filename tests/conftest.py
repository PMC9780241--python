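import numpy as np
import pandas as pd
import pytest

from nadsleep.erp import EpochSet
from nadsleep.recording import ERP_MONTAGE, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_recording(rng):
    """30 s, 21-channel, 500 Hz random recording in µV."""
    fs = 500.0
    data = rng.normal(0.0, 20.0, (len(ERP_MONTAGE), int(30 * fs)))
    return Recording(data, fs, ERP_MONTAGE)


def make_epochs(samples: np.ndarray, fs: float = 500.0,
                t0_ms: float = -100.0, labels: pd.DataFrame | None = None,
                ch_names=None) -> EpochSet:
    """Wrap a trials x channels x time array into an EpochSet."""
    n_tr, n_ch, n_t = samples.shape
    if ch_names is None:
        ch_names = tuple(f"ch{i}" for i in range(n_ch))
    times = t0_ms + np.arange(n_t) * 1000.0 / fs
    if labels is None:
        labels = pd.DataFrame({"trial": np.arange(n_tr)})
    return EpochSet(samples, times, tuple(ch_names), labels,
                    np.ones(n_tr, dtype=bool))
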