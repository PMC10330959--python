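import numpy as np
import pytest

import patchpk as pk


@pytest.fixture(scope="session")
def ref_model():
    """Published final population model (theta, omega, residual)."""
    return pk.reference_model()


@pytest.fixture(scope="session")
def designs():
    return pk.builtin_designs()


@pytest.fixture(scope="session")
def typical_subject(ref_model):
    theta, _, _ = ref_model
    params = pk.individual_params(theta, (0.0, 0.0, 0.0))
    dose = pk.DoseEvent(amount=pk.PATCH_DOSE_NG, t_remove=144.0)
    return params, dose


def small_design(n_subjects=12, times=(0.0, 6, 12, 24, 48, 96, 144, 192), wear=144.0,
                 code="TEST"):
    return pk.StudyDesign(code, n_subjects, pk.PATCH_DOSE_NG, wear,
                          tuple(float(t) for t in times))


@pytest.fixture
def small_dataset(ref_model):
    """Small noisy dataset from the reference model (one compact design)."""
    theta, omega, resid = ref_model
    return pk.simulate_dataset(theta, omega, resid, small_design(), seed=7, lloq=None)
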