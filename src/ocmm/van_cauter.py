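"""Van Cauter population model for C-peptide kinetics.

Predicts the rate constants of the linear two-compartment C-peptide
kinetic model from demographics alone (age and subject class), replacing
an individual C-peptide bolus experiment.  The population model is
parameterized by two exponential half-lives of the plasma decay curve —
a short half-life ``a`` with fractional amplitude ``F`` and a long
half-life ``b`` — from which the three rate constants are reconstructed
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import KineticParams

__all__ = [
    "Demographics",
    "SubjectClass",
    "classify_subject",
    "vc_half_lives",
    "vc_kinetics",
]

#: Valid subject classes of the population model.
SubjectClass = str
_CLASSES = ("normal", "obese", "niddm")

# Short half-life a (min) and fast fraction F by subject class.
_SHORT_HALF_LIFE = {"normal": 4.95, "obese": 4.55, "niddm": 4.52}
_FRACTION = {"normal": 0.76, "obese": 0.78, "niddm": 0.78}

#: BMI (kg/m^2) at or above which a subject is classified obese.
OBESITY_BMI_THRESHOLD = 30.0


@dataclass(frozen=True)
class Demographics:
    """Subject demographics used by the population kinetic model.

    Parameters
    ----------
    age : float
        Age in years, > 0.
    bmi : float
        Body-mass index in kg/m^2, > 0.
    subject_class : str, optional
        One of ``"normal"``, ``"obese"``, ``"niddm"``.  When omitted it
        is derived from BMI via :func:`classify_subject`; NIDDM status
        can only be set explicitly (it is not inferable from BMI).
    """

    age: float
    bmi: float
    subject_class: SubjectClass | None = None

    def __post_init__(self) -> None:
        if not (self.age > 0 and math.isfinite(self.age)):
            raise ValueError(f"age must be positive and finite, got {self.age}")
        if not (self.bmi > 0 and math.isfinite(self.bmi)):
            raise ValueError(f"bmi must be positive and finite, got {self.bmi}")
        if self.subject_class is None:
            object.__setattr__(self, "subject_class", classify_subject(self.bmi))
        elif self.subject_class not in _CLASSES:
            raise ValueError(
                f"subject_class must be one of {_CLASSES}, got {self.subject_class!r}"
            )


def classify_subject(bmi: float, *, niddm: bool = False) -> SubjectClass:
    """Classify a subject as normal / obese / niddm for the kinetic lookup.

    Obesity uses the WHO convention BMI >= 30 kg/m^2.  NIDDM (type-2
    diabetes) cannot be read off BMI and must be flagged explicitly.
    """
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if niddm:
        return "niddm"
    return "obese" if bmi >= OBESITY_BMI_THRESHOLD else "normal"


def vc_half_lives(age: float, subject_class: SubjectClass) -> tuple[float, float, float]:
    """Return ``(a, F, b)``: short half-life (min), fast fraction, long half-life (min).

    ``a`` and ``F`` come from the class lookup; the long half-life grows
    linearly with age, ``b = 0.14*age + 29.2`` min, as in the original
    population study (about 35 min for a middle-aged adult).
    """
    if subject_class not in _CLASSES:
        raise ValueError(
            f"unknown subject class {subject_class!r}; expected one of {_CLASSES}"
        )
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    a = _SHORT_HALF_LIFE[subject_class]
    f = _FRACTION[subject_class]
    b = 0.14 * age + 29.2
    return a, f, b


def vc_kinetics(demographics: Demographics) -> KineticParams:
    """Predict the two-compartment rate constants from demographics.

    With decay rates ``lam_s = ln2/a`` and ``lam_l = ln2/b`` the
    reconstruction is::

        k12 = F*lam_l + (1 - F)*lam_s
        k01 = lam_s*lam_l / k12
        k21 = lam_s + lam_l - k01 - k12

    which guarantees that the impulse response of the resulting
    two-compartment system is the bi-exponential with half-lives
    ``a`` and ``b`` and fast fraction ``F``.
    """
    a, f, b = vc_half_lives(demographics.age, demographics.subject_class)
    lam_s = math.log(2.0) / a
    lam_l = math.log(2.0) / b
    k12 = f * lam_l + (1.0 - f) * lam_s
    k01 = lam_s * lam_l / k12
    k21 = lam_s + lam_l - k01 - k12
    if k21 <= 0:
        raise ValueError(
            "population model yielded non-positive k21 "
            f"(a={a}, F={f}, b={b:.3f} -> k21={k21:.3g}); "
            "half-lives too close for a two-compartment reconstruction"
        )
    return KineticParams(k01=k01, k12=k12, k21=k21)
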