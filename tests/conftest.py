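import numpy as np
import pytest
from hypothesis import settings

import simpull_stoich as ss

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def zscore_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)


def make_separable_set(n: int = 200, length: int = 200,
                       seed: int = 0) -> ss.LabeledTraceSet:
    """Trivially separable 2-class toy: one clean step vs pure noise."""
    rng = np.random.default_rng(seed)
    labels = np.array(["rejected"] * (n // 2) + ["1-step"] * (n - n // 2))
    z = rng.normal(0.0, 1.0, size=(n, length))
    step = np.where(np.arange(length) < length // 2, 1.0, -1.0)
    z[labels == "1-step"] = step + rng.normal(
        0.0, 0.05, size=(int((labels == "1-step").sum()), length))
    return ss.LabeledTraceSet(z, labels, channel=ss.GREEN)


@pytest.fixture(scope="session")
def default_acq():
    return ss.AcquisitionParams()


@pytest.fixture(scope="session")
def farred_model(default_acq):
    """Far-red 4-class CNN trained on 8000 default-SNR synthetic traces."""
    traces, labels = ss.make_labeled_traces(8000, ss.FARRED, default_acq,
                                            seed=1)
    data = ss.LabeledTraceSet(zscore_rows(traces), labels, channel=ss.FARRED)
    model, _ = ss.train(data, ss.ModelConfig(), seed=5)
    return model


@pytest.fixture(scope="session")
def farred_holdout(default_acq):
    traces, labels = ss.make_labeled_traces(2000, ss.FARRED, default_acq,
                                            seed=2)
    return traces, labels


@pytest.fixture(scope="session")
def green_model(default_acq):
    """Green 2-class CNN trained on 3000 default-SNR synthetic traces."""
    traces, labels = ss.make_labeled_traces(3000, ss.GREEN, default_acq,
                                            seed=3)
    data = ss.LabeledTraceSet(zscore_rows(traces), labels, channel=ss.GREEN)
    model, _ = ss.train(data, ss.ModelConfig(n_classes=2, max_epochs=6),
                        seed=6)
    return model
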