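from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def table2_path() -> Path:
    return FIXTURES / "table2_ratings.csv"


@pytest.fixture(scope="session")
def default_params():
    from compsd.params import default_species_params

    return default_species_params()


@pytest.fixture(scope="session")
def succession_pair():
    """Two-species trait trade-off: a fast-growing short-lived shade-intolerant
    pioneer vs a slower, long-lived shade-tolerant climax species."""
    from compsd.params import params_from_frame

    rows = [
        dict(species_code="intol", shade_tolerance_class=1, c1=2.24, c2=1.136,
             cp=0.08, swc_min=0.05, psi=0.5, swc_max=0.95, gdd_min=800,
             gdd_max=2600, g_growth=250, d_max=70, h_max=2800, age_max=90,
             biomass_a=0.1, biomass_b=2.4, recruit_rate=2.0),
        dict(species_code="tol", shade_tolerance_class=5, c1=1.0, c2=4.64,
             cp=0.05, swc_min=0.05, psi=0.5, swc_max=0.95, gdd_min=800,
             gdd_max=2600, g_growth=130, d_max=90, h_max=3100, age_max=400,
             biomass_a=0.1, biomass_b=2.4, recruit_rate=2.0),
    ]
    return params_from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_scenario_stack():
    """A small synthetic landscape with its original-PSD stack and species table."""
    from compsd.pipeline import response_stack
    from compsd.psd import PsdStack, psd_original
    from compsd.synth import SyntheticScenario, generate_species_params, generate_surfaces

    scenario = SyntheticScenario(
        nrows=60, ncols=60, n_species=6, n_plots=400, obs_noise=0.0, seed=11
    )
    par, swc, gdd = generate_surfaces(scenario)
    table = generate_species_params(6, seed=11, gdd_range=scenario.gdd_range)
    responses = response_stack(par, swc, gdd, table)
    stack = PsdStack({c: psd_original(*t) for c, t in responses.items()})
    return scenario, (par, swc, gdd), table, stack
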