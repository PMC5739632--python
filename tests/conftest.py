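"""Shared fixtures: small synthetic cohorts and fits reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

import vancopk as v

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_cov():
    return v.Covariates(BBW=3.22, PNA=29.0)


@pytest.fixture(scope="session")
def final_sp():
    """Structural parameters of the published model at reference covariates
    for the first validation case (BBW 3.9 kg, PNA 23 d)."""
    return v.StructuralParams(V1=1.27, V2=2.422, CL=0.4487, Q=1.161)


@pytest.fixture(scope="session")
def cohort60():
    """A 60-subject synthetic cohort with the default (sparse) design."""
    return v.simulate_cohort(v.CohortSpec(n_subjects=60, seed=101))


@pytest.fixture(scope="session")
def cohort100():
    return v.simulate_cohort(v.CohortSpec(n_subjects=100, seed=202))


@pytest.fixture(scope="session")
def fit100(cohort100):
    return v.fit(v.FINAL_MODEL, cohort100, compute_se=False)


@pytest.fixture(scope="session")
def cohort316():
    """A full-size cohort with the default study design."""
    return v.simulate_cohort(v.CohortSpec(n_subjects=316, seed=47))


@pytest.fixture(scope="session")
def fit316(cohort316):
    return v.fit(v.FINAL_MODEL, cohort316)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
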