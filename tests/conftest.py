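import numpy as np
import pytest

from loopcontact import ChainParameters, ExtrusionSchedule


@pytest.fixture(scope="session")
def chain32() -> ChainParameters:
    """Dimensionless 32-unit linker (b = tau1 = 1)."""
    return ChainParameters(N0=32.0, b=1.0, Ns=1.0, tau1=1.0)


@pytest.fixture(scope="session")
def make_schedule(chain32):
    """Schedule factory: ratio is tau_ex / tau_N0; t0 in units of tau_N0."""

    def factory(ratio_ex_over_relax: float, t0_over_tau_N0: float = 2.0,
                chain: ChainParameters | None = None) -> ExtrusionSchedule:
        c = chain or chain32
        tau_m = ratio_ex_over_relax * c.tau_N0 / c.N0
        return ExtrusionSchedule(chain=c, tau_m=tau_m, t0=t0_over_tau_N0 * c.tau_N0)

    return factory


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
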