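import numpy as np
import pytest

from mapkqsp import fitted
from mapkqsp.core_model import Genotype, SignalingParams, apply_genotype


@pytest.fixture(scope="session")
def base_params() -> SignalingParams:
    return SignalingParams()


@pytest.fixture(scope="session")
def fitted_params() -> SignalingParams:
    return fitted.default_params()


@pytest.fixture(scope="session")
def fitted_ensemble():
    return fitted.load_fitted_ensemble()


@pytest.fixture(scope="session")
def crc_params(fitted_params):
    return apply_genotype(fitted_params,
                          Genotype(("BRAF_V600E",), tissue="CRC"))


@pytest.fixture(scope="session")
def melanoma_params(fitted_params):
    return apply_genotype(fitted_params,
                          Genotype(("BRAF_V600E",), tissue="melanoma"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170602)
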