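import numpy as np
import pytest

from fmisokin import models as M
from fmisokin.synthetic import generate_input_function
from fmisokin.tac import build_schedule, s1_schedule


@pytest.fixture(scope="session")
def input_fn():
    """Default synthetic blood input on the S2 schedule with late frames."""
    return generate_input_function()


@pytest.fixture(scope="session")
def tumor_schedule():
    return s1_schedule()


@pytest.fixture(scope="session")
def coarse_schedule():
    """Small schedule for cheap fitting tests: 12 frames over 45 min + late."""
    from fmisokin.tac import append_late_frames

    sched = build_schedule([(4, 30), (4, 120), (4, 540)], 30)
    return append_late_frames(sched)


@pytest.fixture(scope="session")
def truth_3c5k():
    spec = M.model_spec("3C5K")
    return M.KineticParameters.from_free(spec, [0.08, 0.3, 0.3, 0.05, 0.05, 0.02])


@pytest.fixture(scope="session")
def clean_tac_3c5k(truth_3c5k, input_fn, tumor_schedule):
    return M.model_tac(truth_3c5k.model, truth_3c5k, input_fn, tumor_schedule)


def random_params(model_name, rng, lo=0.02, hi=0.8):
    """Random valid parameter set for any model; rates log-uniform."""
    spec = M.model_spec(model_name)
    free = np.empty(spec.n_free)
    free[0] = rng.uniform(0.02, 0.3)
    free[1:] = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_free - 1))
    return M.KineticParameters.from_free(spec, free)
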