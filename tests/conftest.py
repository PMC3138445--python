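import numpy as np
import pytest

import drugcombo as dc


@pytest.fixture(scope="session")
def panel3():
    return dc.default_three_drug_panel()


@pytest.fixture(scope="session")
def panel4():
    return dc.default_four_drug_panel()


@pytest.fixture(scope="session")
def grid3(panel3):
    return dc.enumerate_grid(panel3)


@pytest.fixture(scope="session")
def grid4(panel4):
    return dc.enumerate_grid(panel4)


@pytest.fixture(scope="session")
def scenario():
    return dc.default_two_celltype_scenario()


@pytest.fixture(scope="session")
def scenario_table(scenario, grid4):
    """Full-grid two-cell-type table at the default plate-noise level."""
    cancer, normal = scenario
    return dc.merge_tables(
        dc.simulate_measurements(cancer, grid4, sigma=0.05, seed=11),
        dc.simulate_measurements(normal, grid4, sigma=0.05, seed=12),
    )


@pytest.fixture(scope="session")
def truth3():
    return dc.default_three_drug_truth()


def constant_model(panel, value):
    """A linear-family model that predicts ``value`` everywhere (intercept only)."""
    n_reg = 2 ** panel.n_drugs - 1
    return dc.FittedResponseModel(
        spec=dc.ModelSpec(family="LR_FULL_INTERACTION"),
        scaler=dc.InputScaler.from_panel(panel),
        params=np.concatenate([[value], np.zeros(n_reg)]),
    )
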