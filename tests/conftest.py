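import numpy as np
import pytest

from oxipredict import (
    ContinuousSegment,
    ModelArchitecture,
    SimConfig,
    TrainingProtocol,
    VitalTrace,
    WindowSpec,
    build_dataset,
    simulate_trace,
    train_model,
)


@pytest.fixture(scope="session")
def sim_trace() -> VitalTrace:
    """A 2000 s synthetic trace with episodes and dropouts."""
    return simulate_trace(SimConfig(duration=2000, seed=11))


@pytest.fixture(scope="session")
def constant_model():
    """Tiny fcnn trained on a constant-95 signal (exactly learnable)."""
    trace = VitalTrace(np.arange(300.0), np.full(300, 95.0))
    spec = WindowSpec(5, 1, 2)
    ds = build_dataset(trace, spec)
    proto = TrainingProtocol(repeats=1, seed=7, max_epochs=5)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_model(ModelArchitecture("fcnn", (8, 4)), ds, proto)
    return model, ds


def make_segment(values, hr=None) -> ContinuousSegment:
    values = np.asarray(values, dtype=float)
    return ContinuousSegment(
        np.arange(len(values), dtype=float),
        values,
        None if hr is None else np.asarray(hr, dtype=float),
    )
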