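import pytest

from myelosim.chemo_toxicity import load_toxicity_table
from myelosim.model_core import CellKineticParameters
from myelosim.regimens import GcsfInjection, get_regimen
from myelosim.sim_engine import SolverSettings


@pytest.fixture(scope="session")
def params():
    return CellKineticParameters.default()


@pytest.fixture(scope="session")
def toxicity_table():
    return load_toxicity_table()


@pytest.fixture(scope="session")
def chop14_elderly():
    return get_regimen("CHOP", risk_group="elderly", cycle_days=14, n_cycles=6)


@pytest.fixture(scope="session")
def fast_solver():
    # coarser output grid for fitting-style workloads; tolerances unchanged
    return SolverSettings(grid_step_day=0.25)


@pytest.fixture
def filgrastim_d4_13():
    return GcsfInjection(derivative="fil", dose=480.0, days=tuple(range(4, 14)))
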