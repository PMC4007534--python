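import pytest
from hypothesis import settings

from endoshrink import pipeline
from endoshrink.synthetic import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


#: study conditions of the main comparison (OIE jitter SD 10 vs nonOIE 2)
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_bundle(default_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return simulate_dataset(default_config, out), out


@pytest.fixture(scope="session")
def pipeline_results(default_bundle, tmp_path_factory):
    _, data_dir = default_bundle
    out = tmp_path_factory.mktemp("results")
    return pipeline.run_all(data_dir, out)


def tiny_config(seed: int, **overrides) -> SimConfig:
    """A minimal but complete dataset: 3 sets over 2+2 species, no census part."""
    kwargs = dict(
        seed=seed,
        n_species_oie=2,
        n_species_nonoie=2,
        n_sets=3,
        base_length_range=(200, 320),
        n_large_accessory_per_nonoie=0,
        n_core_large_pairs=0,
        n_replicates=2,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
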