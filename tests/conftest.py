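import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def codon_table():
    from cpedit import default_codon_table

    return default_codon_table()


@pytest.fixture(scope="session")
def scheme():
    from cpedit import default_property_scheme

    return default_property_scheme()


@pytest.fixture(scope="session")
def small_sim():
    """One default-condition synthetic dataset shared across tests."""
    from cpedit import SimConfig, plant_edits, simulate_genes

    cfg = SimConfig(seed=20260101)
    genes = simulate_genes(cfg)
    transcripts, truth = plant_edits(genes, cfg)
    return cfg, genes, transcripts, truth
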