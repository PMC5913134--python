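import numpy as np
import pytest

from prolylnmr import ExchangeParameters
from prolylnmr.synth import (
    PS110_MIXING_TIMES_MS,
    S110E_MIXING_TIMES_MS,
    SyntheticConfig,
    generate_roesy_dataset,
)

# Apparent catalyzed rates measured for the two peptides (s^-1)
PS110_RATES = {"k_ct": 26.50, "k_tc": 2.48, "k_ex": 28.98, "K_isom_tocsy": 10.7}
S110E_RATES = {"k_ct": 0.73, "k_tc": 0.11, "k_ex": 0.84, "K_isom_tocsy": 6.87}


@pytest.fixture
def ps110_params() -> ExchangeParameters:
    return ExchangeParameters(k_ct=26.50, k_tc=2.48, R2_c=5.0, R2_t=5.0)


@pytest.fixture
def roesy_curve_factory():
    """Factory for (curve, truth) at given rates/noise/seed on a mixing grid."""

    def make(k_ct, k_tc, R2_c=5.0, R2_t=5.0, noise=0.0, seed=0,
             grid=PS110_MIXING_TIMES_MS):
        params = ExchangeParameters(k_ct=k_ct, k_tc=k_tc, R2_c=R2_c, R2_t=R2_t)
        cfg = SyntheticConfig(seed=seed, noise_sd_intensity=noise, mixing_times_ms=grid)
        return generate_roesy_dataset(params, cfg)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
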