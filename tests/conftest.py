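import numpy as np
import pytest

from ctamuscle.phantom import PhantomSpec, SubjectRecord, TissueParams, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A fast 32x32x30 phantom spec for unit tests."""
    defaults = dict(grid_shape=(32, 32, 30), spacing=(3.0, 3.0, 5.0))
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def homogeneous_spec(**overrides) -> PhantomSpec:
    """Small spec with all subject-level heterogeneity switched off."""
    defaults = dict(
        grid_shape=(32, 32, 30),
        between_subject_sd=(0.0, 0.0),
        between_subject_sd_of_sd=(0.0, 0.0),
        distal_gradient=0.0,
        distal_gradient_sd=0.0,
        distal_imf_max=0.0,
        distal_imf_sd=0.0,
        imf_fraction=0.0,
        imf_fraction_sd=0.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def mild_subject() -> SubjectRecord:
    return SubjectRecord("mild_000", "mild", dsa_score=3.0, cta_score=6.0)


@pytest.fixture
def severe_subject() -> SubjectRecord:
    return SubjectRecord("severe_000", "severe", dsa_score=12.0, cta_score=11.0)


@pytest.fixture
def small_phantom(mild_subject):
    """(volume, labels) pair for a small default-parameter mild phantom."""
    return generate_phantom(small_spec(), mild_subject, return_labels=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240327)
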