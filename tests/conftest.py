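import numpy as np
import pytest

from mirsexbias.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_sequences,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=42, n_loci=60, n_clusters=12)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One simulated two-species study shared by read-only tests."""
    ann1, ann2, truth = simulate_annotation(small_config)
    seqs1, seqs2 = simulate_sequences(ann1, ann2, truth, small_config)
    counts2 = simulate_counts(ann2, truth, small_config, design="paired")
    return {
        "config": small_config,
        "ann1": ann1,
        "ann2": ann2,
        "truth": truth,
        "seqs1": seqs1,
        "seqs2": seqs2,
        "counts2": counts2,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
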