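import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ocmm.core import SecretionParams, simulate_ocmm
from ocmm.io import SubjectRecord
from ocmm.synthetic import generate_glucose_profile
from ocmm.van_cauter import Demographics, vc_kinetics

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

OGTT_SCHEDULE = np.array([0, 15, 30, 45, 60, 90, 120, 150, 180, 210], dtype=float)


@pytest.fixture(scope="session")
def phh_signal():
    """A representative post-bypass glucose excursion (peak 9.5, nadir 2.7)."""
    return generate_glucose_profile("OGTT", 5.0, 9.5, 2.7, seed=3)


@pytest.fixture(scope="session")
def demo_normal():
    return Demographics(age=42.0, bmi=28.3)


@pytest.fixture(scope="session")
def noise_free_subject(phh_signal, demo_normal):
    """Subject generated by the model itself with kinetics at the Van Cauter
    prediction and secretion at the estimation-prior medians (inverse-crime
    reference for recovery tests)."""
    vc = vc_kinetics(demo_normal)
    sec = SecretionParams(k_d=3750.0, alpha=0.05, beta=16.0, h=phh_signal.basal)
    cp = simulate_ocmm(vc, sec, phh_signal, OGTT_SCHEDULE, 340.0, method="rk45")
    record = SubjectRecord(
        subject_id="REF",
        demographics=demo_normal,
        test_type="OGTT",
        times=OGTT_SCHEDULE,
        glucose=phh_signal.sample(OGTT_SCHEDULE),
        cpeptide=cp,
    )
    truth = {
        "k_d": 3750.0,
        "alpha": 0.05,
        "beta": 16.0,
        "k01": vc.k01,
        "k12": vc.k12,
        "k21": vc.k21,
    }
    return record, truth
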