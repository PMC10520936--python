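import numpy as np
import pytest

from thzpore import (
    PulseTrain,
    SimulationPlan,
    default_bundle,
    mini_config,
    run,
)


@pytest.fixture(scope="session")
def rat_bundle():
    return default_bundle("rat_neostriatal")


@pytest.fixture(scope="session")
def gp_bundle():
    return default_bundle("guinea_pig_ventricular")


@pytest.fixture(scope="session")
def mini_bundle():
    """Coarse-grid rat configuration for fast coupled runs."""
    return mini_config(0.25)


@pytest.fixture(scope="session")
def reference_plan():
    """The canonical stimulation: 5e7 V/m, 0.5 THz, duty 0.5, 1.2 ns on."""
    return SimulationPlan(
        train=PulseTrain(E0=5e7, f_rep=0.5e12, duty=0.5, t_on=1.2e-9),
        t_end=12.3e-9,
        n_frames=400,
    )


@pytest.fixture(scope="session")
def mini_traj(mini_bundle, reference_plan):
    """One shared coupled reference run on the coarse grid (~10 s)."""
    return run(mini_bundle, reference_plan)


@pytest.fixture()
def theta7():
    return np.linspace(0.0, np.pi, 7)
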