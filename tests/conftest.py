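import numpy as np
import pytest

import spatialp300 as sp
from spatialp300.preprocess import EpochSet


@pytest.fixture(scope="session")
def default_erp() -> sp.ErpModel:
    return sp.ErpModel()


@pytest.fixture(scope="session")
def quiet_noise() -> sp.NoiseModel:
    """No background, no artifacts: recordings contain only ERP templates."""
    return sp.NoiseModel(background_sd=0.0, artifact_rate=0.0)


@pytest.fixture(scope="session")
def small_protocol() -> sp.ProtocolConfig:
    return sp.ProtocolConfig(trials_per_session=40, sessions=2)


def make_epochs(
    data: np.ndarray,
    labels: np.ndarray,
    fs: float = 256.0,
    window_ms=(-100.0, 1100.0),
    directions: np.ndarray | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> EpochSet:
    """Hand-rolled EpochSet for unit tests on small arrays."""
    n, n_ch, _ = data.shape
    if channel_names is None:
        channel_names = sp.CHANNELS_64[:n_ch]
    if directions is None:
        directions = np.full(n, 90, dtype=int)
    return EpochSet(
        epochs=np.asarray(data, float),
        sampling_rate=fs,
        window_ms=window_ms,
        labels=np.asarray(labels, int),
        directions=directions,
        kept_mask=np.ones(n, dtype=bool),
        channel_names=tuple(channel_names),
    )


@pytest.fixture(scope="session")
def synthetic_subject(default_erp):
    """Six preprocessed sessions at the calibrated default noise level.

    Session-scoped: several classification tests share this subject.
    """
    protocol = sp.ProtocolConfig(sessions=6)
    recordings = sp.simulate_subject(protocol, default_erp, sp.NoiseModel(), seed=11)
    epochs, report = sp.preprocess_sessions(recordings)
    return epochs.kept(), report
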