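import pytest

from secircuit.simulate import SimulationConfig, simulate_bundle


def small_sim_config(seed: int = 0) -> SimulationConfig:
    """A reduced bundle used by unit tests (fast: ~2.6 Mb genome)."""
    return SimulationConfig(
        seed=seed, n_chroms=2, chrom_length=1_300_000, n_genes=30,
        n_typical_peaks=60, n_se_model=8, n_se_ea=6,
        shared_se_gene_overlap=2, n_up_model=12, n_up_ea=4,
        candidate_overlap=2, clique_tfs=("TFA", "TFB", "TFC", "TFD"),
        tf_fraction=0.2, n_samples_per_group=6,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(small_sim_config(0))


@pytest.fixture(scope="session")
def default_bundle():
    """One bundle at the full default study conditions."""
    return simulate_bundle(SimulationConfig(seed=0))
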