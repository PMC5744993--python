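import pytest
from hypothesis import HealthCheck, settings

import monoperm as mp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> mp.ModelParameters:
    return mp.ModelParameters()


@pytest.fixture
def neutral() -> mp.SpeciationProfile:
    return mp.SpeciationProfile(f_neutral=1.0)


@pytest.fixture
def cationic() -> mp.SpeciationProfile:
    return mp.SpeciationProfile(f_cation=1.0)


@pytest.fixture
def typical_chemical() -> mp.ChemicalDescriptors:
    """Drug-like neutral solute of moderate size and lipophilicity."""
    return mp.ChemicalDescriptors(
        name="probe", mw=300.0, log_khexw=-2.0, log_klipw=2.5,
        d_aq_37=1e-5, d_hex=5e-6, d_lateral=1e-8,
    )
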