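import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iolbench.biometry_io import BiometryRecord, Cohort
from iolbench.synthetic_data import builtin_profile, generate_cohort

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

#: Fixture eyes spanning short, average and long axial lengths:
#: (AL mm, Km D, ACD mm, implanted IOL power D)
EYE_PANEL = [
    (21.0, 46.0, 2.8, 28.0),
    (22.5, 45.0, 3.0, 24.0),
    (23.5, 43.5, 3.2, 21.0),
    (25.0, 43.0, 3.5, 17.5),
    (26.5, 42.0, 3.7, 14.0),
]


def make_record(
    pid="p1",
    al=23.5,
    km=43.5,
    acd=3.2,
    power=21.0,
    postop=0.0,
    astig=0.5,
    **kw,
) -> BiometryRecord:
    defaults = dict(
        patient_id=pid,
        eye="R",
        age_years=65.0,
        sex="F",
        AL_mm=al,
        ACD_mm=acd,
        LT_mm=4.3,
        CCT_um=540.0,
        WTW_mm=11.9,
        K1_D=km - astig / 2,
        K2_D=km + astig / 2,
        iol_power_D=power,
        postop_ref_D=postop,
        lens_model="SN60WF",
        bscva_at_least_20_40=True,
    )
    defaults.update(kw)
    return BiometryRecord(**defaults)


@pytest.fixture
def panel_cohort() -> Cohort:
    records = [
        make_record(pid=f"e{i}", al=al, km=km, acd=acd, power=p)
        for i, (al, km, acd, p) in enumerate(EYE_PANEL)
    ]
    return Cohort(label="panel", records=records)


@pytest.fixture(scope="session")
def aravind_cohort() -> Cohort:
    """One medium synthetic cohort shared by read-only tests."""
    return generate_cohort(builtin_profile("aravind_like"), 985, seed=20240001)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
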