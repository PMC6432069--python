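import numpy as np
import pytest

from twlc.model import ChainSpec, ParamTable
from twlc.special import TruncationOrder


@pytest.fixture(scope="session")
def table() -> ParamTable:
    return ParamTable.default()


@pytest.fixture(scope="session")
def chain_10kbp() -> ChainSpec:
    return ChainSpec(n_bp=10000, q=1.5)


@pytest.fixture(scope="session")
def chain_small() -> ChainSpec:
    return ChainSpec(n_bp=300, q=1.5)


@pytest.fixture(scope="session")
def trunc_fast() -> TruncationOrder:
    """Truncation adequate for forces up to ~20 pN (validated by the
    convergence test in test_tmatrix)."""
    return TruncationOrder(kmax=24)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
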