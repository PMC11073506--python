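import numpy as np
import pytest

import sigrev as sr


@pytest.fixture(scope="session")
def default_cfg():
    return sr.SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_study(default_cfg):
    """One default-condition study shared across tests (read-only)."""
    study, truth = sr.simulate_expression_study(default_cfg)
    return study, truth


@pytest.fixture(scope="session")
def sim_reference(default_cfg, sim_study):
    study, truth = sim_study
    ref, annotations, vtable = sr.simulate_perturbation_reference(
        default_cfg, truth, study
    )
    return ref, annotations, vtable


@pytest.fixture(scope="session")
def sim_loadings(default_cfg):
    return sr.simulate_latent_loadings(default_cfg)


@pytest.fixture(scope="session")
def nb_de(sim_study):
    study, _ = sim_study
    return sr.nb_glm_de(study)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
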