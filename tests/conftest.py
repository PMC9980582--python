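import pytest

from methclash import Dataset, SimulationConfig, run_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cpg_sites=800, n_fixed_snps=80, n_segregating_snps=80,
        n_true_dmc=60, cluster_geometry=(5, 6, 500), n_genes=20, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    ds = small_dataset
    return run_pipeline(Dataset(ds.samples, ds.calls, ds.snps, ds.genes))
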