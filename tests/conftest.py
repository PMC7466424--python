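import numpy as np
import pytest

from rg4fold.simulate import (
    SimulationConfig,
    generate_transcriptome,
    simulate_rg4seq,
    simulate_shalipe,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def transcriptome(sim_config):
    """Default synthetic transcriptome: (sequences, annotations, truth)."""
    return generate_transcriptome(sim_config)


@pytest.fixture(scope="session")
def rg4_data(transcriptome, sim_config):
    seqs, _, truth = transcriptome
    return {
        cond: simulate_rg4seq(seqs, truth, cond, sim_config)
        for cond in ("Li", "K")
    }


@pytest.fixture(scope="session")
def shalipe_data(transcriptome, sim_config):
    seqs, _, truth = transcriptome
    return {
        state: simulate_shalipe(seqs, truth, state, sim_config)
        for state in ("in_vitro_Li", "in_vitro_K", "in_vivo")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
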