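import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import specembed as se


@pytest.fixture(scope="session")
def reduced_training_data():
    """100 synthetic tryptic peptides x 6 noisy replicates, charge 2."""
    peptides, spectra = se.make_training_set(
        n_peptides=100, n_replicates=6, charge=2, seed=1
    )
    return peptides, spectra


@pytest.fixture(scope="session")
def trained(reduced_training_data):
    """The reduced metric-learning experiment: reduced encoder (2048-dim
    input, base_channels 4), 30 epochs, seed 1.  Shared across tests that
    need a trained embedding model."""
    peptides, spectra = reduced_training_data
    result = se.train(
        spectra,
        se.EncoderConfig.reduced(),
        se.VectorizationConfig.reduced(),
        se.LossConfig(),
        se.TrainingConfig(charge=2, epochs=30, seed=1),
    )
    return peptides, spectra, result


@pytest.fixture()
def tiny_model():
    """An untrained reduced model for structural/inference checks."""
    return se.SpecEmbedModel(
        se.EncoderConfig.reduced(), se.VectorizationConfig.reduced(), charge=2, seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
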