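import numpy as np
import pytest

from petdisplace import (
    DisplacementParams,
    FrameSchedule,
    InputFunctionParams,
    OccupancyProfile,
    REGION_DEFAULTS,
    simulate_displacement,
)
from petdisplace.kinetics import DisplacementModel


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.ucbj_120min()


@pytest.fixture(scope="session")
def true_input():
    """Noise-free tracer input function of the default synthetic subject."""
    return InputFunctionParams().true_input_function(120.0)


@pytest.fixture(scope="session")
def displacement_truth():
    """Seven-region displacement ground truth: V_ND=4, d_max=0.75, ramp 60->75."""
    profile = OccupancyProfile("numerical_ramp", 0.75, 60.0, t_e=75.0)
    return DisplacementParams(regions=REGION_DEFAULTS, v_nd=4.0, occupancy=profile)


@pytest.fixture(scope="session")
def noiseless_tacs(displacement_truth, true_input, schedule):
    return simulate_displacement(displacement_truth, true_input, schedule)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_tacs, true_input):
    """Joint numerical-solution fit of the noiseless seven-region data."""
    return DisplacementModel(
        noiseless_tacs, true_input, t_b=60.0, solution="numerical", seed=0
    ).fit()
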