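import numpy as np
import pytest

from nichesim.params import (ModelParams, SleepSwitchParams, HomeostatParams,
                             PacemakerParams, PhoticParams, RelayMaskingParams)


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams().validate()


@pytest.fixture
def rodent_like() -> ModelParams:
    """Fast-homeostat polyphasic configuration (cheap to simulate)."""
    return ModelParams(
        switch=SleepSwitchParams(noise_sd=0.2),
        homeostat=HomeostatParams(chi=2.0, mu=4.4),
        pacemaker=PacemakerParams(tau_c=24.2),
        photic=PhoticParams(),
        relay=RelayMaskingParams(nu_spz=-1.0, c_offset=1.0, g_dmh_vlpo=8.0),
    ).validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
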