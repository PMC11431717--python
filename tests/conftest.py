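import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from platequant import simulate

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def op50_quiet():
    """OP50-like parameters with the noise switched off (deterministic)."""
    return dataclasses.replace(simulate.strain_preset("OP50-like"), noise_cv=0.0)


@pytest.fixture
def op50_noisy():
    """OP50-like parameters at the default 1% multiplicative OD noise."""
    return simulate.strain_preset("OP50-like")
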