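import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blendspec as bs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_spectra() -> bs.SpectraSet:
    """Two samples on a 3-channel grid with spacing 8."""
    return bs.SpectraSet(
        np.array([4000.0, 4008.0, 4016.0]),
        np.array([[1.0, 2.0, 3.0], [0.5, 0.25, 0.125]]),
        ["S1", "S2"],
    )


@pytest.fixture(scope="session")
def default_endmembers() -> bs.EndmemberSet:
    return bs.generate_endmembers(bs.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def nir_experiment() -> bs.ExperimentResult:
    """The full synthetic NIR study at the default generator settings,
    seed 1: 87-sample design, all six varieties modelled, unknowns screened.

    Session-scoped because it backs several end-to-end assertions.
    """
    return bs.run_full_experiment(
        bs.GeneratorConfig(seed=1), bs.WorkflowConfig(seed=1)
    )
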