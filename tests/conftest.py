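import numpy as np
import pytest

import germclock as g


@pytest.fixture(scope="session")
def small_design():
    return g.CohortDesign(n_per_cell=3)


@pytest.fixture(scope="session")
def small_params():
    # desk-scale array: 15 regions of 20 CpGs, 5 carrying age signal
    return g.SimulationParams(
        n_cpgs=300,
        cpgs_per_region=20,
        n_clock_regions=5,
        age_slope_sd=0.02,
        noise_sd=0.3,
        bmi_acceleration_years=0.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_design, small_params):
    cohort = g.generate_cohort(small_design, seed=11)
    beta, region_map, truth = g.simulate_methylome(cohort, small_params, seed=11)
    return cohort, beta, region_map, truth


@pytest.fixture(scope="session", autouse=True)
def warm_cd_kernel():
    """Compile the coordinate-descent kernel once so timed tests measure math, not JIT."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 3))
    X = (X - X.mean(0)) / X.std(0)
    g.fit_elastic_net(X, rng.normal(size=8), alpha=0.5, lam=0.1)
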