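import numpy as np
import pytest

from wristsim import (
    ControllerConfig,
    Motion,
    Posture,
    extract_grid_forces,
    generate_trajectory,
    gravity_torque,
    run_controller,
)
from wristsim.errors import ConfigurationError, DivergenceError
from wristsim.moment_arms import estimate_specimen_moment_arms
from wristsim.specimens import MUSCLES

from conftest import constant_trajectory


def test_gravity_torque_closed_form(specimen):
    neutral = gravity_torque(Posture(0.0, 0.0), specimen)
    assert (neutral.tau_fe, neutral.tau_rud) == (0.0, 0.0)
    # m g d at 90 deg: 0.45 * 9.81 * 60 = 264.87 N*mm
    t = gravity_torque(Posture(90.0, 0.0), specimen)
    assert abs(t.tau_fe) == pytest.approx(
        specimen.hand_mass * 9.81 * specimen.hand_com_distance, rel=1e-12
    )
    # odd function of each angle
    for ang in (10.0, 37.0):
        plus = gravity_torque(Posture(ang, ang / 2), specimen)
        minus = gravity_torque(Posture(-ang, -ang / 2), specimen)
        assert plus.tau_fe == pytest.approx(-minus.tau_fe)
        assert plus.tau_rud == pytest.approx(-minus.tau_rud)


def test_hold_neutral_without_gravity_rests_at_lower_bounds(specimen):
    traj = constant_trajectory(0.0, 0.0, cycles=2)
    result = run_controller(specimen, traj, ControllerConfig(gravity_on=False))
    lo, hi = specimen.f_bounds()
    f_end = result.forces[-1]
    # net demanded torque ~ 0 and forces just above minimal tone
    assert np.abs(result.torque_demands[-1]).max() < 1.0
    assert np.all(f_end >= lo - 1e-9)
    assert np.max(f_end - lo) < 0.05 * hi.max()


def test_ablated_muscle_produces_exactly_zero_force(fe5030_pair):
    _, ablated = fe5030_pair
    assert ablated.muscle_force("APL").max() == 0.0
    assert ablated.condition == "apl_ablated"


def test_bounds_satisfied_at_every_step(fe5030_pair):
    intact, ablated = fe5030_pair
    for result in fe5030_pair:
        lo, hi = result_bounds(result)
        assert np.all(result.forces <= hi[None, :] + 1e-9)
        mask = np.ones(len(MUSCLES), bool)
        if result.condition == "apl_ablated":
            mask[MUSCLES.index("APL")] = False
        assert np.all(result.forces[:, mask] >= lo[None, mask] - 1e-9)


def result_bounds(result):
    # bounds recorded implicitly via the fixture's specimen
    from wristsim import CohortParams, make_specimen

    spec = make_specimen(1, CohortParams())
    return spec.f_bounds()


def test_run_is_deterministic(specimen):
    traj = generate_trajectory(Motion.RUD15, cycles=2)
    a = run_controller(specimen, traj, ControllerConfig())
    b = run_controller(specimen, traj, ControllerConfig())
    assert np.array_equal(a.forces, b.forces)
    assert np.array_equal(a.postures, b.postures)


def test_steady_state_cycles_are_periodic(fe5030_pair):
    intact, _ = fe5030_pair
    c1 = intact.forces[intact.cycle_slice(1)]
    c2 = intact.forces[intact.cycle_slice(2)]
    rms = np.sqrt(np.mean((c1 - c2) ** 2))
    scale = np.sqrt(np.mean(c1**2))
    assert rms / scale < 0.01


def test_tracking_error_within_tolerance(fe5030_pair):
    intact, _ = fe5030_pair
    assert intact.rms_tracking_error() <= 1.0


def test_quasi_static_agrees_with_stiff_dynamic(specimen):
    traj = generate_trajectory(Motion.FE5030, cycles=3)
    quasi = run_controller(specimen, traj, ControllerConfig(mode="quasi_static"))
    stiff = run_controller(specimen, traj, ControllerConfig(natural_freq_hz=6.0))
    gq = extract_grid_forces(quasi).set_index(["muscle", "grid_value"])["force"]
    gd = extract_grid_forces(stiff).set_index(["muscle", "grid_value"])["force"]
    rel = np.abs(gq - gd) / np.abs(gq)
    assert rel.max() < 0.05


def test_estimated_moment_arms_reproduce_true_forces_closely(specimen):
    traj = generate_trajectory(Motion.RUD15, cycles=2)
    true_run = run_controller(specimen, traj, ControllerConfig())
    fits = estimate_specimen_moment_arms(specimen, noise_sigma=0.05, seed=3)
    est_run = run_controller(
        specimen, traj, ControllerConfig(), moment_arm_source="estimated", ma_fits=fits
    )
    denom = max(1.0, np.abs(true_run.forces).max())
    assert np.max(np.abs(true_run.forces - est_run.forces)) / denom < 0.10


def test_antagonist_unloads_when_apl_ablated(small_cohort):
    """In RUD15, removing APL lowers the mean ECU force for every specimen."""
    traj = generate_trajectory(Motion.RUD15, cycles=3)
    for spec in small_cohort:
        intact = run_controller(spec, traj, ControllerConfig())
        ablated = run_controller(spec, traj, ControllerConfig(ablation={"APL"}))
        sl = intact.steady_state_slice()
        ecu_intact = intact.muscle_force("ECU")[sl].mean()
        ecu_ablated = ablated.muscle_force("ECU")[sl].mean()
        assert ecu_ablated < ecu_intact
        # and the synergists pick up load
        assert ablated.muscle_force("FCR")[sl].mean() > intact.muscle_force("FCR")[sl].mean()
        assert ablated.muscle_force("ECRL")[sl].mean() > intact.muscle_force("ECRL")[sl].mean()


def test_divergence_raises(specimen):
    traj = generate_trajectory(Motion.FE5030, cycles=1)
    with pytest.raises(DivergenceError):
        run_controller(
            specimen, traj,
            ControllerConfig(kp=0.0, kd=0.0, gravity_feedforward=False),
        )


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ControllerConfig(dt=0.01)
    ControllerConfig(dt=0.01, allow_coarse_dt=True)  # override allowed
    with pytest.raises(ConfigurationError):
        ControllerConfig(ablation=set(MUSCLES))
    with pytest.raises(ConfigurationError):
        ControllerConfig(ablation={"BICEPS"})
    with pytest.raises(ConfigurationError):
        ControllerConfig(mode="static")
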