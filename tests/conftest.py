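import numpy as np
import pytest
from hypothesis import settings

from urimet import (
    CohortConfig,
    align_spectra,
    bucket_spectra,
    oplsda_fit,
    pqn_normalize,
    rebin,
    simulate_cohort,
    uv_scale,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


class PreparedCohort:
    """A simulated cohort taken through the preprocessing chain once."""

    def __init__(self, config, align=True):
        self.config = config
        self.spectra, self.truth = simulate_cohort(config)
        self.fine = bucket_spectra(self.spectra, 0.001)
        self.aligned = align_spectra(self.fine, 50) if align else self.fine
        self.normalized, self.dilution = pqn_normalize(self.aligned)
        self.coarse = rebin(self.normalized, 10)
        self.scaled, self.scaling = uv_scale(self.coarse)
        self.y = np.asarray(self.coarse.groups)


@pytest.fixture(scope="session")
def strong_cohort():
    """Default study conditions: 51 BPH vs 64 PCa with the planted fold changes."""
    return PreparedCohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def strong_model_cv(strong_cohort):
    from urimet import cross_validate

    model = oplsda_fit(strong_cohort.scaled.values, strong_cohort.y, 1)
    cv = cross_validate(strong_cohort.scaled.values, strong_cohort.y, 1, 7, seed=5)
    return model, cv


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 8v8 cohort for cheap unit tests."""
    return PreparedCohort(CohortConfig(n_group_a=8, n_group_b=8, seed=3), align=False)


def two_class_matrix(rng, n, k):
    """Random matrix with valid two-class labels (each class >= 2)."""
    X = rng.normal(size=(n, k))
    while True:
        y = np.array(["A", "B"])[rng.integers(0, 2, n)]
        if min((y == "A").sum(), (y == "B").sum()) >= 2:
            return X, y
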