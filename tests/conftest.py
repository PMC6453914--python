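import pytest

from hybmode.classify import classify_all
from hybmode.preprocess import make_profile
from hybmode.synthetic import (
    SimConfig,
    low_noise_config,
    simulate_ase,
    simulate_counts,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small default-noise simulated dataset shared across tests."""
    cfg = SimConfig(n_genes=400, seed=7)
    truth = simulate_truth(cfg)
    matrix = simulate_counts(truth, cfg)
    ase = simulate_ase(truth, matrix, cfg)
    return cfg, truth, matrix, ase


@pytest.fixture(scope="session")
def low_noise_calls():
    """10k-gene low-noise simulation classified in all four groups."""
    cfg = low_noise_config(n_genes=10000, seed=11)
    truth = simulate_truth(cfg)
    matrix = simulate_counts(truth, cfg)
    profile = make_profile(matrix)
    calls, counts = classify_all(profile)
    return truth, profile, calls, counts
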