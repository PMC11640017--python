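import numpy as np
import pandas as pd
import pytest

from survtv import Cohort, GeneratorConfig, TimeGrid, generate_cohort
from survtv.simulate import N_AE_CATEGORIES, PATIENT_COLUMNS, VISIT_COLUMNS


def make_patient(pid, diagnosis=0, duration=10, event=1, age=76.0, race=0,
                 er=1, pr=1, her2=0, grade=2, histology=0, comorb=1.0):
    return dict(zip(PATIENT_COLUMNS, [pid, diagnosis, duration, event, age,
                                      race, er, pr, her2, grade, histology, comorb]))


def make_visit(pid, month, chemo=0, bio=0, hormone=0, aes=(), comorb=1.0):
    ae_flags = [1 if k in aes else 0 for k in range(1, N_AE_CATEGORIES + 1)]
    return dict(zip(VISIT_COLUMNS, [pid, month, chemo, bio, hormone, *ae_flags, comorb]))


def build_cohort(patient_rows, visit_rows, n_intervals=60):
    patients = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    return Cohort(patients=patients, visits=visits, grid=TimeGrid(n_intervals=n_intervals))


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient default-configuration synthetic cohort (shared, read-only)."""
    return generate_cohort(GeneratorConfig(n_patients=300, seed=42))


@pytest.fixture
def toy_cohort():
    """Hand-built 3-patient cohort with known visit histories."""
    patients = [
        make_patient("A", diagnosis=0, duration=8, event=1, comorb=2.0),
        make_patient("B", diagnosis=5, duration=12, event=0, age=82.0, grade=3, comorb=0.0),
        make_patient("C", diagnosis=2, duration=20, event=1, age=68.0, er=0, comorb=1.0),
    ]
    visits = [
        make_visit("A", 0, comorb=2.0),
        make_visit("A", 2, chemo=1, comorb=2.0),
        make_visit("A", 5, chemo=1, aes=(3,), comorb=3.0),
        make_visit("B", 5, comorb=0.0),
        make_visit("C", 2, comorb=1.0),
        make_visit("C", 4, hormone=1, comorb=1.0),
        make_visit("C", 9, bio=1, aes=(1, 7), comorb=2.0),
        make_visit("C", 15, comorb=2.0),
    ]
    return build_cohort(patients, visits)


def random_survival_matrix(rng, n, times):
    """Random valid (non-increasing) survival curves on a shared grid."""
    steps = rng.random((n, times.size))
    S = np.cumprod(1.0 - 0.3 * steps, axis=1)
    return S
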