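import numpy as np
import pytest

import ordidrift as od


@pytest.fixture(scope="session")
def stature_in():
    """9-category 1-inch stature grid centred at 58 in."""
    return od.make_equal_interval_thresholds(58.0, 1.0, 9, unit="in")


@pytest.fixture(scope="session")
def model_in():
    """Worked-example latent model in inches: N(58, 1.87^2), sigma_u2 = 10 cm^2."""
    sy2 = 1.87**2
    su2 = 10.0 / od.CM_PER_INCH**2
    return od.LatentTraitModel(58.0, su2, sy2 - su2, unit="in")


@pytest.fixture(scope="session")
def model_cm():
    return od.report.paper_projection_model("cm")


@pytest.fixture(scope="session")
def stature_cm():
    return od.report.stature_thresholds("EI1", "cm")


@pytest.fixture(scope="session")
def small_pedigree():
    return od.generate_pedigree(n_founders=30, n_generations=2,
                                offspring_per_mating=2, seed=7)


@pytest.fixture(scope="session")
def scenario_study():
    """The simulation study at reference size: ~12.9k-animal pedigree,
    ~5,141 records, 10 replicates of the five scenarios.  Shared session
    fixture because the Gibbs chains dominate the suite's run time."""
    ped = od.pedsim.default_pedigree_preset(seed=0)
    model = od.report.simulation_model("cm")
    ts = od.report.stature_thresholds("EI1", "cm")
    cfg = od.GibbsConfig(n_iter=8_000, burn_in=1_500, thin=5, seed=0,
                         n_replicates=10)
    return od.run_scenarios(ped, model, ts, c=5.0, config=cfg)
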