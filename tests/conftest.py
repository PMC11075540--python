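import numpy as np
import pytest
from hypothesis import settings

from tecurate.classify import train_order_model
from tecurate.pipeline import PipelineConfig, run_curation_pipeline
from tecurate.profiles import build_profile
from tecurate.simulate import (
    SIM_TE_DOMAINS,
    GeneratorConfig,
    gen_library,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def sim_library(sim_config):
    return gen_library(sim_config)


@pytest.fixture(scope="session")
def te_profiles(sim_library):
    return [
        build_profile(aln, name, *SIM_TE_DOMAINS[name])
        for name, aln in sorted(sim_library.te_domain_alignments.items())
    ]


@pytest.fixture(scope="session")
def expanded_profiles(sim_library):
    return [
        build_profile(aln, name, "expanded")
        for name, aln in sorted(sim_library.expanded_alignments.items())
    ]


@pytest.fixture(scope="session")
def order_model(sim_library):
    return train_order_model(
        sim_library.training_records, sim_library.training_labels
    )


@pytest.fixture(scope="session")
def pipeline_result(sim_library, te_profiles, expanded_profiles, order_model):
    return run_curation_pipeline(
        PipelineConfig(seed=1),
        records=sim_library.records,
        order_model=order_model,
        te_profiles=te_profiles,
        expanded_profiles=expanded_profiles,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
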