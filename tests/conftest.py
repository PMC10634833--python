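import numpy as np
import pytest

from commassembly import (
    GeneratorConfig,
    make_toy_model,
    metabolic_similarity,
)


@pytest.fixture(scope="session")
def t1():
    """The fixed hand-checkable toy model and its three environments."""
    model, envs = make_toy_model("T1")
    return model, envs


@pytest.fixture(scope="session")
def t1_sim(t1):
    model, envs = t1
    return metabolic_similarity(model, envs)


@pytest.fixture(scope="session")
def branched20():
    """A 20-substrate branched toy network and its similarity matrix."""
    model, envs = make_toy_model("branched", k=20, seed=11)
    sim = metabolic_similarity(model, envs)
    return model, envs, sim


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(seed=7, n_strains=12, n_substrates=6, n_taxa=24)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
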