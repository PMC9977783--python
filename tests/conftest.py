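import pytest

from hdxflex.synthetic import (
    SynthConfig,
    digest,
    generate_ground_truth,
    generate_toy_ensemble,
    simulate_centroids,
)


@pytest.fixture(scope="session")
def zero_noise_study():
    """A deterministic noise-free study with 20% planted class shifts."""
    cfg = SynthConfig(seed=5, noise_sd=0.0, frac_shifted_residues=0.2)
    truth = generate_ground_truth(cfg)
    peptides = digest(truth.sequence, cfg)
    centroids = simulate_centroids(truth, peptides, cfg)
    return cfg, truth, peptides, centroids


@pytest.fixture(scope="session")
def noisy_study():
    cfg = SynthConfig(seed=11, noise_sd=0.1, frac_shifted_residues=0.2)
    truth = generate_ground_truth(cfg)
    peptides = digest(truth.sequence, cfg)
    centroids = simulate_centroids(truth, peptides, cfg)
    return cfg, truth, peptides, centroids


@pytest.fixture(scope="session")
def toy_ensemble():
    return generate_toy_ensemble(n_structures=10, n_planted_waters=3, seed=7)
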