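import pytest

from jipclust import default_calibration, generate_cohort
from jipclust.preprocess import fit_transform


@pytest.fixture(scope="session")
def default_config():
    return default_calibration()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """A 400-patient labeled cohort for fast unit tests."""
    return generate_cohort(default_config, seed=42, n_patients=400)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return fit_transform(small_cohort.cohort)


@pytest.fixture(scope="session")
def study_cohort(default_config):
    """The full-size analysis cohort (n=1387, one fixed seed)."""
    return generate_cohort(default_config, seed=1, n_patients=1387)


@pytest.fixture(scope="session")
def fitted_pipeline(study_cohort):
    """One trained end-to-end cluster model, shared across tests that
    exercise recovery, stability and projection."""
    from jipclust.cluster import JIPClusterPipeline
    return JIPClusterPipeline(random_state=1).fit(study_cohort.cohort)
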