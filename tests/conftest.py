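import numpy as np
import pytest

import carbonflux as cf


@pytest.fixture(scope="session")
def scenario_small():
    """60×60 landscape, 200 plots — shared across read-only tests."""
    spec = cf.ScenarioSpec(grid_shape=(60, 60), n_plots=200, seed=3)
    return cf.generate_scenario(spec)


@pytest.fixture(scope="session")
def design_small(scenario_small):
    plots = cf.prepare(scenario_small.plots)
    stack = cf.CovariateStack.from_scenario(scenario_small)
    retained = cf.screen_collinearity(stack, seed=1)
    design = cf.extract_at_plots(stack, plots, retained=retained)
    return stack, design, plots


@pytest.fixture(scope="session")
def fitted_small(design_small):
    """Fitted ensemble on the small scenario (expensive; reused)."""
    stack, design, plots = design_small
    results = cf.CarbonFluxModel(design, seed=7).fit()
    return stack, design, plots, results


@pytest.fixture
def rng():
    return np.random.default_rng(42)
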