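import math

import pytest
from hypothesis import HealthCheck, settings

from mts import CharacteristicCurves, MusculotendonParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curves() -> CharacteristicCurves:
    return CharacteristicCurves()


@pytest.fixture
def unpennated() -> MusculotendonParams:
    """Simple fusiform muscle: no pennation, tendon 0.35 m."""
    return MusculotendonParams(
        f_iso_max=1000.0, l_opt_f=0.05, alpha_opt=0.0, l_opt_mt=0.40, name="fusiform"
    )


@pytest.fixture
def pennated() -> MusculotendonParams:
    """Soleus-like pennated muscle with volume-derived force capacity."""
    sigma, volume, l_opt_f = 61.0, 500.0, 0.05
    return MusculotendonParams(
        f_iso_max=sigma * volume / (l_opt_f * 100.0),
        l_opt_f=l_opt_f,
        alpha_opt=math.radians(25.0),
        l_opt_mt=0.40,
        sigma_iso_max=sigma,
        volume=volume,
        name="pennated",
    )


def stratified_grid():
    """The stratified parameter/state grid used for oracle-equivalence and
    ranking checks: pennation x tendon ratio x activation x fiber length."""
    for alpha_deg in (0.0, 10.0, 20.0, 30.0):
        for ratio in (3.0, 5.0, 10.0):
            for a in (0.0, 0.5, 1.0):
                l_opt_f = 0.05
                params = MusculotendonParams(
                    f_iso_max=1500.0,
                    l_opt_f=l_opt_f,
                    alpha_opt=math.radians(alpha_deg),
                    l_opt_mt=ratio * l_opt_f,
                )
                yield params, a
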