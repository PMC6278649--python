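from __future__ import annotations

import numpy as np
import pytest

from bzfit import ExchangeRateParams, ModelParams


@pytest.fixture
def default_rates() -> ExchangeRateParams:
    return ExchangeRateParams(kex_B=50.0, kex_BP=20.0, kex_ZP=10.0, kex_ZP2=1.0)


@pytest.fixture
def pkz_params() -> ModelParams:
    """caZa_PKZ constants at pH 6.0, 10 mM NaCl."""
    return ModelParams(Kd_BP=0.028, Kd_ZP2=0.345, K_BZ1=0.87)


@pytest.fixture
def tight_params() -> ModelParams:
    """Tight-binding, K_BZ1 = 1: the half-stoichiometry regime."""
    return ModelParams(Kd_BP=1e-4, Kd_ZP2=1e-6, K_BZ1=1.0)


@pytest.fixture
def chi_grid_20() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(0.1, 2.0, 20), 6))
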