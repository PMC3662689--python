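"""Shared fixtures: experiment designs and precomputed equivalent-radius tables.

The unit tables are built once per session (they tabulate quadrature
root-finds over the internal-model parameter grid) and rescaled per
subject, which keeps the simulation-heavy tests affordable.
"""

import warnings

import numpy as np
import pytest

from motormodel import ExperimentDesign
from motormodel.internal_model import EquivalentRadiusTable


@pytest.fixture(scope="session")
def exp1_design() -> ExperimentDesign:
    return ExperimentDesign.experiment_1()


@pytest.fixture(scope="session")
def exp2_design() -> ExperimentDesign:
    return ExperimentDesign.experiment_2()


@pytest.fixture(scope="session")
def unit_table_exp1(exp1_design) -> EquivalentRadiusTable:
    return EquivalentRadiusTable(exp1_design.rectangles(1.0), 1.0)


@pytest.fixture(scope="session")
def unit_table_exp2(exp2_design) -> EquivalentRadiusTable:
    return EquivalentRadiusTable(exp2_design.rectangles(1.0), 1.0)


@pytest.fixture(scope="session")
def nested_simulation(exp2_design, unit_table_exp2) -> dict:
    """One shared nested bootstrap simulation (100 subjects × 200 replicates).

    Simulates Gaussian-type subjects whose internal model equals the true
    variance with isotropic shape (σ̃² = σ², η̃ = 1 against true η = 1.44),
    runs the full pipeline with bootstrap CIs for each, and tallies CI
    coverage of the generating ratios and the classification outcomes.
    Several acceptance checks consume these tallies.
    """
    from motormodel import SubjectSpec
    from motormodel.pipeline import run_subject

    n_outer, n_boot = 100, 200
    cov_s2 = cov_eta = n_gauss = 0
    for s in range(n_outer):
        rep = run_subject(SubjectSpec(seed=5000 + s), exp2_design,
                          n_boot=n_boot, unit_table=unit_table_exp2)
        n_gauss += rep["internal_model"]["type"] == "gaussian"
        lo, hi = rep["bootstrap"]["ci_sigma2_ratio"]
        cov_s2 += lo <= 1.0 <= hi          # generating σ̃² equals σ²
        lo, hi = rep["bootstrap"]["ci_eta_ratio"]
        cov_eta += lo <= 1.0 / 1.44 <= hi  # generating η̃ = 1, true η = 1.44
    return {"n_outer": n_outer, "n_boot": n_boot, "cov_sigma2": cov_s2,
            "cov_eta": cov_eta, "n_classified_gaussian": n_gauss}


@pytest.fixture(autouse=True)
def _quiet_separable_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
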