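import numpy as np
import pytest

from pleiobgs.pipeline import RunConfig, run_analysis
from pleiobgs.simulate import GeneratorConfig, generate_bundle


def small_generator_config(seed: int = 11) -> GeneratorConfig:
    """A desk-scale bundle: 150 genes, 8 robust traits, degrees up to 6."""
    return GeneratorConfig(seed=seed, n_genes=150, n_traits=8,
                           n_noise_traits=2, max_degree=6)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_bundle(small_generator_config(), outdir)


def run_config_for(bundle, **overrides) -> RunConfig:
    defaults = dict(
        catalog=bundle["paths"]["catalog"],
        genes=bundle["paths"]["genes_bed"],
        b_track=bundle["paths"]["b_track"],
        genetic_map=bundle["paths"]["genetic_map"],
        prevalence=bundle["prevalence"],
        domains=bundle["domains"],
        min_genes=10,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def small_run(small_bundle):
    return run_analysis(run_config_for(small_bundle))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
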