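import numpy as np
import pytest

try:  # keep linear algebra single-threaded: small-matrix workloads thrash
    from threadpoolctl import threadpool_limits

    threadpool_limits(1)
except ImportError:  # pragma: no cover
    pass

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_lstm_spec():
    from deepconvlstm import ModelSpec

    return ModelSpec(
        variant="lstm", n_channels=2, n_classes=3, window_len=17,
        n_maps=3, n_hidden=4,
    )


@pytest.fixture
def tiny_cnn_spec():
    from deepconvlstm import ModelSpec

    return ModelSpec(
        variant="cnn", n_channels=2, n_classes=3, window_len=17,
        n_maps=3, n_hidden=4,
    )
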