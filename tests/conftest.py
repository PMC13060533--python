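import numpy as np
import pytest

from coarsematch import (
    Cohort,
    calibrate_spec,
    generate_cohort,
    study1_spec,
    study2_spec,
)


@pytest.fixture(scope="session")
def study2_calibrated():
    """Binary-outcome spec with intercepts resolved once for the session."""
    return calibrate_spec(study2_spec(), seed=11)


@pytest.fixture(scope="session")
def study2_cohort(study2_calibrated):
    return generate_cohort(study2_calibrated, 10_000, seed=21)


@pytest.fixture(scope="session")
def study1_cohort():
    return generate_cohort(study1_spec(), 10_000, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_cohort(x1, x2, t, y):
    return Cohort(
        np.asarray(x1, float), np.asarray(x2, float),
        np.asarray(t, float), np.asarray(y, float),
    )
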