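import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wristsim import (
    CohortParams,
    ControllerConfig,
    MuscleSpec,
    Specimen,
    Trajectory,
    generate_trajectory,
    make_cohort,
    make_specimen,
)
from wristsim.trajectories import Motion


@pytest.fixture(scope="session")
def specimen():
    """A default-parameter specimen at a fixed seed."""
    return make_specimen(1, CohortParams())


@pytest.fixture(scope="session")
def mean_specimen():
    """Zero-variance specimen: every parameter equals the cohort mean."""
    return make_specimen(0, CohortParams(cv=0.0))


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(3, base_seed=7)


def constant_trajectory(theta_fe=0.0, theta_rud=0.0, cycles=2, period=1.0, dt=0.0045):
    """A stationary 'motion': the target holds one posture for all cycles."""
    ref = generate_trajectory(Motion.FE5030, cycles=cycles, period=period, dt=dt)
    zeros = np.zeros_like(ref.times)
    return Trajectory(
        motion=ref.motion,
        dt=ref.dt,
        period=ref.period,
        cycles=ref.cycles,
        times=ref.times,
        theta_fe=np.full_like(ref.times, theta_fe),
        theta_rud=np.full_like(ref.times, theta_rud),
        omega_fe=zeros,
        omega_rud=zeros.copy(),
        alpha_fe=zeros.copy(),
        alpha_rud=zeros.copy(),
        cycle_boundaries=ref.cycle_boundaries,
    )


@pytest.fixture(scope="session")
def fe5030_pair(specimen):
    """Intact and APL-ablated FE5030 runs of the default specimen."""
    from wristsim import run_controller

    traj = generate_trajectory(Motion.FE5030, cycles=3)
    intact = run_controller(specimen, traj, ControllerConfig())
    ablated = run_controller(specimen, traj, ControllerConfig(ablation={"APL"}))
    return intact, ablated
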