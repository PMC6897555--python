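import numpy as np
import pandas as pd
import pytest

from cplearn.erp import EpochArray
from cplearn.stimuli import build_tiles, make_scheme, make_set, sample_rating_pairs


@pytest.fixture(scope="session")
def tiles():
    return build_tiles(seed=0)


@pytest.fixture(scope="session")
def scheme_k4():
    return make_scheme(4, seed=0)


@pytest.fixture(scope="session")
def small_set(scheme_k4):
    # 40 stimuli keep texture generation cheap while allowing rating pairs
    return make_set(scheme_k4, n=40, seed=0)


@pytest.fixture(scope="session")
def rating_pairs(small_set):
    return sample_rating_pairs(small_set, seed=0)


def make_epochs(
    data: np.ndarray,
    sfreq: float = 100.0,
    tmin: float = -0.2,
    ch_names=None,
    subject_id: str = "test",
) -> EpochArray:
    """Wrap a channels × samples × trials array in an EpochArray."""
    n_ch, n_samp, n_tr = data.shape
    if ch_names is None:
        ch_names = tuple(f"C{i}" for i in range(n_ch))
    tmax = tmin + n_samp / sfreq
    return EpochArray(
        subject_id=subject_id,
        data=np.asarray(data, dtype=float),
        ch_names=tuple(ch_names),
        sfreq=sfreq,
        tmin=tmin,
        tmax=tmax,
        metadata=pd.DataFrame({"trial": np.arange(1, n_tr + 1)}),
    )


@pytest.fixture
def epochs_factory():
    return make_epochs
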