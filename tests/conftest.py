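import numpy as np
import pytest

from trlocus.simulate import (
    default_config,
    references_for,
    simulate_locus,
    simulate_transcripts,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default study-conditions locus (seeded) with ground truth."""
    config = default_config(seed=11)
    annotation, truth = simulate_locus(config)
    return config, annotation, truth


@pytest.fixture(scope="session")
def default_references(default_sim):
    config, _, _ = default_sim
    return references_for(config)


@pytest.fixture(scope="session")
def default_transcripts(default_sim):
    config, annotation, truth = default_sim
    transcripts, truth = simulate_transcripts(annotation, truth, config)
    return transcripts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
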