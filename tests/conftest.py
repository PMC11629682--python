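import pytest

from mecphage.pipeline import PipelineConfig, run_all
from mecphage.synth import SynthConfig, generate_dataset

# Small, fast configuration used by most unit tests.
SMALL_KWARGS = dict(
    n_mecs=3,
    n_host_species=8,
    n_phage_species=8,
    bins_per_species=(1, 2),
    genome_size_range=(15_000, 22_000),
    contigs_per_genome=(2, 3),
    phage_size_range=(6_000, 9_000),
    spacers_per_array=(3, 4),
    completeness_range=(85.0, 100.0),
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(**SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_config):
    d = tmp_path_factory.mktemp("synth") / "data"
    generate_dataset(small_config, d)
    return d


@pytest.fixture(scope="session")
def small_pipeline(small_dataset_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("results")
    config = PipelineConfig(
        input_dir=str(small_dataset_dir),
        output_dir=str(out),
        group_size=10,
        n_perm=199,
    )
    result = run_all(config)
    return config, result
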