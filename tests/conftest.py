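import numpy as np
import pytest

from canesacc import load_fixtures
from canesacc.design import CCDDesign, FactorScale, build_ccd


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def printed_design(fixtures):
    """The packaged 11-run design exactly as published (run 2 nonstandard)."""
    return fixtures.design


@pytest.fixture(scope="session")
def std_design(printed_design):
    """The same design snapped to the textbook CCD layout."""
    return printed_design.as_standard()


@pytest.fixture(scope="session")
def responses(fixtures):
    return fixtures.responses


@pytest.fixture(scope="session")
def validation(fixtures):
    return fixtures.validation


@pytest.fixture(scope="session")
def ethanol_scale():
    return FactorScale("ethanol", "% v/v", 65.0, 30.0, 100.0, alpha=1.41)


@pytest.fixture(scope="session")
def time_scale():
    return FactorScale("time", "min", 120.0, 0.0, 240.0, alpha=1.41)


@pytest.fixture(scope="session")
def unit_factors():
    """Two generic factors with unit coded steps, for synthetic designs."""
    return [
        FactorScale("f1", "u", 0.0, -1.41, 1.41, alpha=1.41),
        FactorScale("f2", "u", 0.0, -1.41, 1.41, alpha=1.41),
    ]


@pytest.fixture(scope="session")
def unit_design(unit_factors):
    return build_ccd(unit_factors, n_center=3)


def random_quadratic_fit(design: CCDDesign, rng: np.random.Generator, noise=0.0):
    """Fit to a random surface sampled on the design (test helper)."""
    from canesacc.rsm import COEF_NAMES, ResponseTable, fit_quadratic
    import pandas as pd

    beta = rng.normal(0.0, 3.0, size=6)
    x = design.coded_matrix
    y = (
        beta[0]
        + beta[1] * x[:, 0]
        + beta[2] * x[:, 1]
        + beta[3] * x[:, 0] ** 2
        + beta[4] * x[:, 1] ** 2
        + beta[5] * x[:, 0] * x[:, 1]
    )
    y = y + rng.normal(0.0, noise, size=len(y)) + 100.0  # keep positive
    df = pd.DataFrame(
        {
            "run_id": design.run_ids,
            "genotype": "SIM",
            "timepoint": "t",
            "rep": 1,
            "value": y,
        }
    )
    fit = fit_quadratic(design, ResponseTable(df), "SIM", "t")
    true = dict(zip(COEF_NAMES, beta))
    true["b0"] += 100.0
    return fit, true
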