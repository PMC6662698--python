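import warnings

import numpy as np
import pytest

import attractormem as am

warnings.filterwarnings("ignore", category=RuntimeWarning, module="attractormem")


@pytest.fixture(scope="session")
def grid100():
    return am.Grid(100)


@pytest.fixture(scope="session")
def basis12(grid100):
    return am.build_basis(12, grid100)


@pytest.fixture(scope="session")
def drift4(grid100):
    """Canonical four-attractor drift field (SFPs at 0/90/180/270 deg)."""
    return am.four_attractor_field(grid100)


@pytest.fixture(scope="session")
def truth():
    return am.default_truth()


@pytest.fixture(scope="session")
def small_dataset(truth):
    """600 trials, loads 1 and 3, delays 1 and 7 s, from the canonical truth."""
    design = am.TaskDesign(n_trials_per_condition=150)
    return am.simulate_trials(truth, design, seed=321)


@pytest.fixture(scope="session")
def strong_drift_dataset(drift4):
    """Load-1 data with strong drift and no guesses/swaps: the cleanest
    setting for the model-free bias/precision signatures."""
    dyn = am.DynamicsParams(beta={1: 2.0}, sigma={1: 0.2},
                            beta_star={1: 2.0}, sigma_star={1: 0.2})
    mix = am.MixtureParams(guess_slope={1: 0.0}, guess_intercept={1: 0.0})
    gt = am.GroundTruth(drift4, dyn, mix)
    design = am.TaskDesign(loads=(1,), delays_s=(1.0, 7.0),
                           n_trials_per_condition=3000)
    return am.simulate_trials(gt, design, seed=99)
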