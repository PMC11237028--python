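import numpy as np
import pytest

from nfabt import build_default_schema, make_cohort
from nfabt.cohort import RiskParams


@pytest.fixture(scope="session")
def default_schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients x 5 days, fully observed, logistic labels."""
    return make_cohort(n=12, horizon=5, seed=7, missingness=False)


@pytest.fixture(scope="session")
def missing_cohort():
    """20 patients x 6 days with default per-feature missingness."""
    return make_cohort(n=20, horizon=6, seed=11, missingness=True)


@pytest.fixture(scope="session")
def labeled_cohort_98():
    """Default-size cohort without missingness, for the fuzzy/robustness stages."""
    return make_cohort(n=98, seed=1, missingness=False)


@pytest.fixture(scope="session")
def trend_cohort_arrays():
    """Hemoglobin sequences with a purely trend-dependent daily label."""
    from nfabt.bench import cohort_arrays

    c = make_cohort(n=40, horizon=10, seed=3, missingness=False, risk_params=RiskParams(mode="trend"))
    return cohort_arrays(c, features=("hgb",))
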