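import numpy as np
import pytest

from chematlas import (
    SyntheticSpec,
    TrainingConfig,
    fingerprint_matrix,
    generate_dataset,
    standardize_all,
    train,
)


@pytest.fixture(scope="session")
def three_scaffold_spec():
    """A small 3-scaffold library spec shared across the suite."""
    return SyntheticSpec(n_scaffolds=3, per_scaffold=50, seed=7)


@pytest.fixture(scope="session")
def library(three_scaffold_spec):
    return generate_dataset(three_scaffold_spec)


@pytest.fixture(scope="session")
def records(library):
    return standardize_all(library["smiles"])


@pytest.fixture(scope="session")
def fingerprints(records):
    return fingerprint_matrix(records)


@pytest.fixture(scope="session")
def scaffold_labels(library):
    return library["scaffold_id"].to_numpy()


@pytest.fixture(scope="session")
def tiny_model(fingerprints):
    """A quickly trained small projector for determinism / IO tests."""
    cfg = TrainingConfig(
        perplexity=20, batch_size=75, epochs=25, seed=3, hidden_dims=(64, 64)
    )
    return train(fingerprints, cfg)
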