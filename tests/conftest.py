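import numpy as np
import pandas as pd
import pytest

import radonmap as rm


@pytest.fixture(scope="session")
def small_grid():
    return rm.GridSpec(nx=10, ny=10)


@pytest.fixture(scope="session")
def calibrated_params():
    return rm.calibrate_field_params()


@pytest.fixture(scope="session")
def quadrant_regions():
    grid = rm.GridSpec(nx=10, ny=10)
    return rm.make_regions(grid, 4, mode="blocks")


@pytest.fixture()
def toy_strata():
    """Three regions, one sex, two age bands — hand-checkable numbers."""
    rows = []
    data = {
        (1, "0-4"): (100, 2), (1, "5-9"): (200, 1),
        (2, "0-4"): (300, 3), (2, "5-9"): (100, 2),
        (3, "0-4"): (100, 1), (3, "5-9"): (200, 3),
    }
    for (rid, ag), (pop, obs) in data.items():
        rows.append({"region_id": rid, "sex": "male", "age_group": ag,
                     "population": pop, "observed": obs})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def simulated_dataset():
    """One small end-to-end synthetic data set shared across tests."""
    grid = rm.GridSpec(nx=20, ny=20)
    params = rm.calibrate_field_params()
    log_field = rm.simulate_log_field(grid, params, 101)
    regions = rm.make_regions(grid, 30, seed=102)
    radon = rm.aggregate_to_regions(np.exp(log_field), regions)["radon_bqm3"].to_numpy()
    covariates = rm.synthetic.make_region_covariates(regions, radon, seed=103)
    truth = rm.TruthRecord(beta_radon=float(np.log(1.07)), sigma_u=0.1,
                           sigma_v=0.05, seed=104)
    strata = rm.simulate_strata_and_counts(regions, covariates, truth, seed=104)
    return {
        "grid": grid, "params": params, "log_field": log_field,
        "regions": regions, "radon": radon, "covariates": covariates,
        "truth": truth, "strata": strata,
    }
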