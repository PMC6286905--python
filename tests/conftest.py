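import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from prrtplan import (
    GeneratorConfig,
    LinearModelFit,
    fit_reference_models,
    generate_cohort,
)
from prrtplan.cohort import with_no_dropout


@pytest.fixture(scope="session")
def clean_cohort():
    """A no-dropout cohort large enough for stable regression fits."""
    cfg = with_no_dropout(GeneratorConfig(n_patients=4000, seed=11))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_models(clean_cohort):
    fits = fit_reference_models(clean_cohort)
    # the planning logic assumes doses push risk upward; make sure the
    # fixture satisfies that before any monotonicity-style test uses it
    for fit in fits.values():
        assert (fit.coefficients[1:] > 0).all()
    return fits


@pytest.fixture(scope="session")
def noiseless_fits():
    """Deterministic fits with the reference coefficients and zero noise."""
    return {
        "simple": LinearModelFit.from_coefficients(("D1",), [2.0, 3.0]),
        "joint34": LinearModelFit.from_coefficients(("D1", "D2"), [1.39, 0.56, 1.19]),
        "d3": LinearModelFit.from_coefficients(("D1", "D2"), [0.37, 0.14, 0.83]),
        "d4": LinearModelFit.from_coefficients(("D1", "D2", "D3"), [0.99, 0.12, 0.19, 0.50]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
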