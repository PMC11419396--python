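import pytest

from oscmux import TrainConfig, build_training_set, train_network

CANONICAL_SEED = 0


@pytest.fixture(scope="session")
def canonical_dataset():
    return build_training_set(CANONICAL_SEED)


@pytest.fixture(scope="session")
def trained(canonical_dataset):
    """Weights and loss trace of one canonical training run (shared session-wide)."""
    weights, trace = train_network(
        canonical_dataset, TrainConfig(seed=CANONICAL_SEED)
    )
    return weights, trace
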