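import numpy as np
import pytest

from embryostack.learners import BoosterConfig
from embryostack.hierarchical_model import fit_hierarchical_model
from embryostack.synthetic_cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, sized for fast training in unit tests."""
    return generate_cohort(default_config(1200, seed=11))


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    return fit_hierarchical_model(small_cohort, BoosterConfig(seed=7))


@pytest.fixture(scope="session")
def patient_embryo_pool(small_cohort):
    """Patients and a flat embryo pool for random selection instances."""
    patients = [r.patient for r in small_cohort]
    embryos = [e for r in small_cohort for e in r.embryos]
    return patients, embryos


def make_instance(rng: np.random.Generator, patients, embryos, k: int):
    """One random selection instance: a patient and k distinct embryos."""
    patient = patients[rng.integers(len(patients))]
    idx = rng.choice(len(embryos), size=k, replace=False)
    return patient, [embryos[i] for i in idx]
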