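import numpy as np
import pytest

import txapk as tx


@pytest.fixture(scope="session")
def truth():
    """The default generating truth: published fixed effects, config variances."""
    return tx.default_truth()


@pytest.fixture(scope="session")
def cohort77(truth):
    """One full-size synthetic cohort under the study design."""
    return tx.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def cohort77_eval(truth, cohort77):
    """The full cohort evaluated at its own generating parameters."""
    return tx.evaluate(cohort77, truth.model, truth.params)


@pytest.fixture(scope="session")
def small_cohort(truth):
    """A 12-subject cohort for fast fitting tests."""
    return tx.simulate_dataset(tx.CohortDesign(n=12), truth, seed=7)


@pytest.fixture(scope="session")
def onecomp_truth():
    """A one-compartment generating truth (no covariates) for cheap experiments."""
    model = tx.PopModelSpec(n_compartments=1, covariate_effects=(), iiv=("cl1", "v1"))
    params = tx.ParamSet(
        theta={"v1": 12.77, "cl1": 3.263},
        omega2={"cl1": 0.09, "v1": 0.09},
        sigma=tx.SigmaParams(1.0, 0.15),
    )
    return tx.TruthParams(model, params)
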