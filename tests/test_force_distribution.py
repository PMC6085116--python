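import numpy as np
import pytest

from wristsim import DistributionProblem, TorqueDemand, feasible_torque_set, solve_distribution
from wristsim.errors import InfeasibleTorqueError, InputValidationError
from wristsim.force_distribution import CubedStress, contains_torque, make_criterion

from oracles import active_set_qp_oracle, random_distribution_instance


def make_problem(R, lo, hi, tau, criterion=None):
    return DistributionProblem(
        moment_arm_matrix=np.asarray(R, float),
        f_min=np.asarray(lo, float),
        f_max=np.asarray(hi, float),
        demand=TorqueDemand(*tau),
        criterion=criterion,
    )


def test_single_muscle_unique_solution():
    state = solve_distribution(make_problem([[10.0], [0.0]], [0.0], [100.0], (50.0, 0.0)))
    assert state.forces == pytest.approx([5.0])
    assert state.residual <= 1e-9


def test_opposing_muscles_zero_demand_costs_nothing():
    state = solve_distribution(
        make_problem([[10.0, -10.0], [0.0, 0.0]], [0.0, 0.0], [100.0, 100.0], (0.0, 0.0))
    )
    assert state.forces == pytest.approx([0.0, 0.0])
    assert state.cost == 0.0


def test_solver_matches_active_set_oracle():
    rng = np.random.default_rng(42)
    for _ in range(120):
        R, lo, hi, tau = random_distribution_instance(rng)
        state = solve_distribution(make_problem(R, lo, hi, tau))
        f_oracle, cost_oracle = active_set_qp_oracle(R, lo, hi, tau, hi)
        assert f_oracle is not None
        assert state.cost == pytest.approx(cost_oracle, rel=1e-6, abs=1e-9)
        assert state.residual <= 1e-6 * max(1.0, np.abs(tau).max())
        assert np.all(state.forces >= lo - 1e-9) and np.all(state.forces <= hi + 1e-9)


def test_infeasible_demand_raises_with_closest_torque():
    R = np.array([[10.0, 0.0], [0.0, 10.0]])
    with pytest.raises(InfeasibleTorqueError) as exc:
        solve_distribution(make_problem(R, [0.0, 0.0], [1.0, 1.0], (500.0, 500.0)))
    assert exc.value.closest == pytest.approx([10.0, 10.0])


def test_feasibility_verdicts_agree_with_zonotope():
    """solve_distribution and the vertex zonotope agree on every verdict."""
    rng = np.random.default_rng(7)
    for _ in range(60):
        R, lo, hi, _ = random_distribution_instance(rng, m=4)
        verts = feasible_torque_set(R, lo, hi)
        for feasible in (True, False):
            _, _, _, tau = random_distribution_instance(rng, m=4, feasible=feasible)
            if feasible:
                tau = R @ rng.uniform(lo, hi)
            inside = contains_torque(verts, tau, tol=1e-9)
            try:
                solve_distribution(make_problem(R, lo, hi, tau))
                verdict = True
            except InfeasibleTorqueError:
                verdict = False
            assert verdict == inside


def test_zonotope_trivial_geometries():
    seg = feasible_torque_set([[10.0], [0.0]], [0.0], [5.0])
    assert sorted(map(tuple, seg)) == [(0.0, 0.0), (50.0, 0.0)]
    square = feasible_torque_set([[10.0, 0.0], [0.0, 10.0]], [0.0, 0.0], [1.0, 1.0])
    assert sorted(map(tuple, square)) == [(0.0, 0.0), (0.0, 10.0), (10.0, 0.0), (10.0, 10.0)]


def test_ablation_never_decreases_cost():
    """Removing a muscle (zero lower bounds) can only raise the optimal effort."""
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 40:
        R, lo, hi, tau = random_distribution_instance(rng, m=4, zero_lower=True)
        full = solve_distribution(make_problem(R, lo, hi, tau))
        drop = rng.integers(0, 4)
        keep = [j for j in range(4) if j != drop]
        try:
            reduced = solve_distribution(
                DistributionProblem(
                    moment_arm_matrix=R[:, keep],
                    f_min=lo[keep],
                    f_max=hi[keep],
                    demand=TorqueDemand(*tau),
                    criterion=make_criterion("normalized_quadratic", hi[keep]),
                )
            )
        except InfeasibleTorqueError:
            continue
        assert reduced.cost >= full.cost - 1e-8 * max(full.cost, 1.0)
        checked += 1


def test_scaling_homogeneity():
    """Scaling demand and bounds by c scales the optimal forces by c."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        R, lo, hi, tau = random_distribution_instance(rng, m=3)
        base = solve_distribution(make_problem(R, lo, hi, tau))
        c = 3.7
        scaled = solve_distribution(make_problem(R, c * lo, c * hi, tuple(c * np.asarray(tau))))
        assert scaled.forces == pytest.approx(c * base.forces, rel=1e-6, abs=1e-8)


def test_cubed_stress_criterion_solves_and_balances():
    rng = np.random.default_rng(13)
    for _ in range(30):
        R, lo, hi, tau = random_distribution_instance(rng, m=4)
        pcsa = rng.uniform(1.5, 4.0, 4)
        state = solve_distribution(
            make_problem(R, lo, hi, tau, criterion=CubedStress(pcsa))
        )
        assert state.residual <= 1e-6 * max(1.0, np.abs(tau).max())
        assert np.all(state.forces >= lo - 1e-9) and np.all(state.forces <= hi + 1e-9)
        # optimality spot check against random feasible perturbations in the null space
        assert state.cost <= CubedStress(pcsa).cost(np.clip(state.forces, lo, hi)) + 1e-9


def test_validation_errors():
    with pytest.raises(InputValidationError):
        make_problem([[0.0], [0.0]], [0.0], [10.0], (1.0, 0.0))  # all-zero column
    with pytest.raises(InputValidationError):
        make_problem([[10.0], [0.0]], [5.0], [5.0], (1.0, 0.0))  # f_min >= f_max
    with pytest.raises(InputValidationError):
        TorqueDemand(np.inf, 0.0)
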