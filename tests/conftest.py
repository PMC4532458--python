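import numpy as np
import pytest

import facemorph as fm


@pytest.fixture(scope="session")
def grid_x():
    return np.linspace(0.0, 1.0, 11)


@pytest.fixture(scope="session")
def exp1_trials():
    """Small masking-experiment simulation: 6 observers, 2 runs, with RTs."""
    sched = fm.build_schedule(1, n_participants=6, n_runs=2, seed=11)
    return fm.simulate(sched, fm.SimConfig.exp1_defaults(seed=42), emit_rt=True)


@pytest.fixture(scope="session")
def exp2_trials():
    """Small composite-face simulation: 6 observers, 1 run per block."""
    sched = fm.build_schedule(2, n_participants=6, n_runs=1, seed=12)
    return fm.simulate(sched, fm.SimConfig.exp2_defaults(seed=43))
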