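import pytest

from ernalink.pipeline import run_pipeline
from ernalink.synthetic_data import SimulationConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """Full synthetic study at the default scale, seed 1."""
    return generate(seed=1)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Pipeline run over the default synthetic study."""
    return run_pipeline(default_dataset, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast per-test simulation."""
    return SimulationConfig(
        n_chromosomes=1,
        chrom_length_bp=720_000,
        n_tads_per_chrom=4,
        n_genes=40,
        n_planted_enhancers=12,
        n_nonmacrophage_enhancers=16,
        n_decoy_peak_pairs=10,
        n_background_samples=30,
        n_responsive_ifng=3,
        n_responsive_il4=3,
        n_decoy_tfs=4,
        n_exclusion_intervals=6,
        rng_seed=11,
    )
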