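import numpy as np
import pytest

from txroadblock.kinetics import K_U_OID, KineticParams


@pytest.fixture(scope="session")
def oid_params() -> KineticParams:
    """Ideal-operator condition at 250 nM repressor with the fitted rates
    (ideal-operator-only fit: k_T = 0.066, k_SD = 0.0015, k_MD = 0.026)."""
    return KineticParams(
        k_F=3.3e-4,
        k_B=0.6275,
        k_U=K_U_OID,
        k_T=0.066,
        k_SD=0.0015,
        k_MD=0.026,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140717)
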