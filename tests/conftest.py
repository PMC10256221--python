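import logging

import pytest

from phagepop.model import ExperimentConfig, ModelParams

# class-cap warnings are expected under high-mutation-rate prior draws
logging.getLogger("phagepop.model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ms2_like_params() -> ModelParams:
    """Parameters near the point estimates reported for the MS2 experiment."""
    return ModelParams(w_s=0.9, w_ns=0.7, w_b=1.8, p_bs=0.005, p_bns=0.005,
                       M_s=0.5, M_ns=0.8, delta=1.0, eta=-0.3, U=0.2)


@pytest.fixture(scope="session")
def small_config() -> ExperimentConfig:
    """A cheap experiment: small population, modest coverage, 10 passages."""
    return ExperimentConfig(N=10_000, coverage={3: 300, 7: 300, 10: 300})


@pytest.fixture(scope="session")
def toy_annotation():
    from phagepop.hapio import make_toy_annotation

    return make_toy_annotation(seed=3, n_codons_gene1=60)
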