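"""Shared fixtures: synthetic models, patients and small cohorts."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import meromipd as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def standard_male():
    """The standard typical patient used throughout: 55 y male, 80 kg."""
    return m.CovariateSet(age=55.0, sex="male", weight_total=80.0, weight_ideal=70.0,
                          height=180.0, serum_creatinine=100.0, albumin=25.0,
                          apache_ii=24.0, crp=100.0)


@pytest.fixture
def one_cpt_params():
    """Typical 1-compartment values of a published sepsis model (CL 16.7, V 30.7)."""
    return m.StructuralParams(cl=16.7, vc=30.7)


@pytest.fixture
def two_cpt_params():
    return m.StructuralParams(cl=10.0, vc=12.0, q2=15.0, vp2=12.0)


@pytest.fixture
def single_infusion():
    """One gram infused over 30 minutes starting at t = 0."""
    return [m.DoseEvent(0.0, 1000.0, 0.5)]


@pytest.fixture
def generator_model():
    return m.default_generator_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient synthetic cohort at the default (study-like) design."""
    return m.generate_cohort(m.CohortDesign(n_patients=20), seed=0)


@pytest.fixture
def simple_1cpt_spec():
    """Fully specified synthetic 1-compartment model with known variances."""
    return m.ModelSpec(
        name="simple_1cpt",
        theta=m.StructuralParams(cl=10.0, vc=25.0),
        relations=[],
        eta_names=("cl",),
        omega=np.array([[0.09]]),
        residual=m.ResidualErrorModel("additive", sigma_add=0.5),
    )
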