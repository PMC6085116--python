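"""Closed-loop two-axis wrist plant and controller.

The hand segment is modelled as a point mass on a massless link with
decoupled principal inertias about the FE and RUD axes. With the hand in
the vertically upward orientation, gravity exerts the restoring torque
tau_g = -m g d sin(theta) about each axis (zero at neutral, odd in the
angle), treating the two axes independently (small-coupling approximation).

Per control step (default dt = 4.5 ms, matching a 4-5 ms real-time loop):

1. the torque demand is PD position feedback on the trajectory target plus
   exact gravity-compensation feedforward;
2. the force-distribution solver realizes the demand across the non-ablated
   muscles within their physiological bounds;
3. in ``dynamic`` mode the plant is integrated with semi-implicit Euler
   (inertia * acc = muscle torque + gravity - viscous damping); in
   ``quasi_static`` mode the posture snaps to the target and the demand is
   the inverse-dynamics torque of the reference motion.

Ablating a muscle removes its column from every distribution problem, so
its recorded force is exactly zero for the whole motion - the software
equivalent of switching off and slackening its actuator.

Units: torques N*mm, inertia kg*mm^2, angles stored in degrees; note
1 N*mm = 1000 kg*mm^2/s^2, hence the factor 1000 in the acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DivergenceError,
    InfeasibleTorqueError,
    InputValidationError,
)
from .force_distribution import (
    DistributionProblem,
    TorqueDemand,
    make_criterion,
    solve_distribution,
)
from .moment_arms import MomentArmFit
from .specimens import MUSCLES, Specimen
from .trajectories import Motion, Posture, Trajectory

__all__ = ["ControllerConfig", "SimulationResult", "gravity_torque", "run_controller"]

_G = 9.81  # m/s^2; with mass in kg and lever in mm, m*g*d is N*mm
_NMM_PER_KGMM2 = 1000.0  # acceleration (rad/s^2) = 1000 * tau[N*mm] / I[kg*mm^2]
_DIVERGENCE_DEG = 20.0


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, timing, and experimental condition of one simulation run.

    ``kp``/``kd`` (N*mm/deg, N*mm*s/deg) default to per-specimen pole
    placement: critically damped response at ``natural_freq_hz`` per axis,
    accounting for the plant's own viscous damping. ``ablation`` lists
    muscles forced inactive (zero force throughout). ``mode`` selects the
    dynamic closed loop or the quasi-static inverse-dynamics shortcut.
    """

    kp: float | None = None
    kd: float | None = None
    dt: float = 0.0045
    gravity_on: bool = True
    gravity_feedforward: bool = True
    ablation: frozenset[str] = frozenset()
    mode: str = "dynamic"
    natural_freq_hz: float = 3.0
    criterion: str = "normalized_quadratic"
    allow_coarse_dt: bool = False

    def __post_init__(self):
        object.__setattr__(self, "ablation", frozenset(self.ablation))
        if self.mode not in ("dynamic", "quasi_static"):
            raise ConfigurationError(f"mode must be 'dynamic' or 'quasi_static', got {self.mode!r}")
        if (self.kp is not None and self.kp < 0) or (self.kd is not None and self.kd < 0):
            raise ConfigurationError("kp and kd must be >= 0")
        if not self.allow_coarse_dt and not (0.004 <= self.dt <= 0.005):
            raise ConfigurationError(
                f"dt = {self.dt} s outside the 4-5 ms control-loop range "
                "(set allow_coarse_dt to override)"
            )
        unknown = self.ablation - set(MUSCLES)
        if unknown:
            raise ConfigurationError(f"unknown muscles in ablation set: {sorted(unknown)}")
        if len(self.ablation) >= len(MUSCLES):
            raise ConfigurationError("cannot ablate every muscle")
        if self.natural_freq_hz <= 0:
            raise ConfigurationError("natural_freq_hz must be > 0")


@dataclass
class SimulationResult:
    """Time series of one (specimen, motion, condition) run.

    ``forces`` is (n_steps, 6) in canonical muscle order with ablated
    columns identically zero; ``postures``/``target_postures`` are
    (n_steps, 2) in degrees; ``torque_demands`` (n_steps, 2) in N*mm;
    ``tracking_error`` per-step Euclidean angle error (deg).
    """

    motion: Motion
    specimen_id: str
    condition: str
    times: np.ndarray
    postures: np.ndarray
    target_postures: np.ndarray
    torque_demands: np.ndarray
    forces: np.ndarray
    tracking_error: np.ndarray
    infeasible_steps: int
    cycle_boundaries: tuple[int, ...]
    dt: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_boundaries) - 1

    def cycle_slice(self, k: int) -> slice:
        return slice(self.cycle_boundaries[k], self.cycle_boundaries[k + 1] + 1)

    def steady_state_slice(self) -> slice:
        """Samples after the first (transient) cycle."""
        if self.n_cycles < 2:
            return slice(0, len(self.times))
        return slice(self.cycle_boundaries[1], len(self.times))

    def rms_tracking_error(self, steady_only: bool = True) -> float:
        sl = self.steady_state_slice() if steady_only else slice(None)
        return float(np.sqrt(np.mean(self.tracking_error[sl] ** 2)))

    def muscle_force(self, muscle: str) -> np.ndarray:
        return self.forces[:, MUSCLES.index(muscle)]

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (time, muscle)."""
        n = len(self.times)
        n_per_cycle = self.cycle_boundaries[1] - self.cycle_boundaries[0]
        cycle = np.minimum(np.arange(n) // n_per_cycle, self.n_cycles - 1)
        frames = []
        for j, m in enumerate(MUSCLES):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "muscle": m,
                        "force_N": self.forces[:, j],
                        "theta_fe": self.postures[:, 0],
                        "theta_rud": self.postures[:, 1],
                        "condition": self.condition,
                        "specimen": self.specimen_id,
                        "motion": self.motion.value,
                        "cycle": cycle,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def gravity_torque(posture: Posture, specimen: Specimen) -> TorqueDemand:
    """Gravitational torque (N*mm) about each axis at the given posture.

    Vertically-upward hand configuration: tau_g = -m g d sin(theta) per
    axis; zero at neutral and an odd function of each angle.
    """
    mgd = specimen.hand_mass * _G * specimen.hand_com_distance
    return TorqueDemand(
        tau_fe=-mgd * np.sin(np.radians(posture.theta_fe)),
        tau_rud=-mgd * np.sin(np.radians(posture.theta_rud)),
    )


def _moment_arm_coeffs(
    specimen: Specimen,
    source: str,
    ma_fits: Mapping[tuple[str, str], MomentArmFit] | None,
    order: tuple[str, ...],
):
    """Padded ascending coefficient arrays (2, m, deg+1) for fast evaluation."""
    coeffs = {"FE": [], "RUD": []}
    for m in order:
        for axis in ("FE", "RUD"):
            if source == "true":
                spec = specimen.muscle(m)
                c = spec.ma_fe if axis == "FE" else spec.ma_rud
            elif source == "estimated":
                if ma_fits is None or (m, axis) not in ma_fits:
                    raise InputValidationError(
                        "moment_arm_source='estimated' requires ma_fits covering all "
                        f"(muscle, axis) pairs; missing {(m, axis)}"
                    )
                c = ma_fits[(m, axis)].coefficients
            else:
                raise ConfigurationError(f"moment_arm_source must be 'true' or 'estimated', got {source!r}")
            coeffs[axis].append(np.asarray(c, dtype=float))
    deg = max(max(c.size for c in coeffs["FE"]), max(c.size for c in coeffs["RUD"]))
    C = np.zeros((2, len(order), deg))
    for j in range(len(order)):
        C[0, j, : coeffs["FE"][j].size] = coeffs["FE"][j]
        C[1, j, : coeffs["RUD"][j].size] = coeffs["RUD"][j]
    return C


def _eval_R(C: np.ndarray, theta_fe_rad: float, theta_rud_rad: float) -> np.ndarray:
    deg = C.shape[2]
    pow_fe = theta_fe_rad ** np.arange(deg)
    pow_rud = theta_rud_rad ** np.arange(deg)
    R = np.empty((2, C.shape[1]))
    R[0] = C[0] @ pow_fe
    R[1] = C[1] @ pow_rud
    return R


def run_controller(
    specimen: Specimen,
    trajectory: Trajectory,
    config: ControllerConfig = ControllerConfig(),
    moment_arm_source: str = "true",
    ma_fits: Mapping[tuple[str, str], MomentArmFit] | None = None,
    condition: str | None = None,
) -> SimulationResult:
    """Drive the specimen through the trajectory and record muscle forces.

    ``moment_arm_source`` selects the specimen's true moment-arm polynomials
    ('true') or tendon-excursion fits supplied in ``ma_fits`` ('estimated'),
    mirroring the workflow of measuring specimen-specific moment arms
    passively before active simulation.
    """
    active = tuple(m for m in MUSCLES if m not in config.ablation)
    active_idx = np.array([MUSCLES.index(m) for m in active])
    C = _moment_arm_coeffs(specimen, moment_arm_source, ma_fits, active)
    lo, hi = specimen.f_bounds(active)
    pcsa = np.array([specimen.muscle(m).pcsa for m in active])
    crit = make_criterion(config.criterion, hi, pcsa)

    inertia = np.array([specimen.hand_inertia_fe, specimen.hand_inertia_rud])
    damping = np.array([specimen.damping_fe, specimen.damping_rud])
    mgd = specimen.hand_mass * _G * specimen.hand_com_distance

    wn = 2 * np.pi * config.natural_freq_hz
    # pole placement (per rad); config gains given per degree
    kp = (
        np.full(2, config.kp * 180.0 / np.pi)
        if config.kp is not None
        else inertia * wn * wn / _NMM_PER_KGMM2
    )
    kd = (
        np.full(2, config.kd * 180.0 / np.pi)
        if config.kd is not None
        else np.maximum(2.0 * inertia * wn / _NMM_PER_KGMM2 - damping, 0.0)
    )

    n = len(trajectory)
    target = np.column_stack([trajectory.theta_fe, trajectory.theta_rud])
    target_vel = np.column_stack([trajectory.omega_fe, trajectory.omega_rud])
    target_acc = np.column_stack([trajectory.alpha_fe, trajectory.alpha_rud])

    postures = np.empty((n, 2))
    demands = np.empty((n, 2))
    forces = np.zeros((n, len(MUSCLES)))
    tracking = np.empty(n)
    infeasible = 0
    dt = trajectory.dt
    deg2rad = np.pi / 180.0

    theta = target[0].copy()  # deg
    vel = target_vel[0].copy()  # deg/s
    lam = None

    quasi = config.mode == "quasi_static"
    for i in range(n):
        if quasi:
            theta = target[i]
            vel = target_vel[i]
        theta_rad = theta * deg2rad
        tau_g = -mgd * np.sin(theta_rad) if config.gravity_on else np.zeros(2)
        if quasi:
            tau = (
                inertia * (target_acc[i] * deg2rad) / _NMM_PER_KGMM2
                + damping * (target_vel[i] * deg2rad)
                - tau_g
            )
        else:
            err = target[i] - theta
            derr = target_vel[i] - vel
            tau = kp * (err * deg2rad) + kd * (derr * deg2rad)
            if config.gravity_feedforward:
                tau = tau - tau_g
        problem = DistributionProblem(
            moment_arm_matrix=_eval_R(C, theta_rad[0], theta_rad[1]),
            f_min=lo,
            f_max=hi,
            demand=TorqueDemand(float(tau[0]), float(tau[1])),
            active=active,
            criterion=crit,
        )
        try:
            state = solve_distribution(problem, warm_start=lam)
        except InfeasibleTorqueError as exc:
            infeasible += 1
            achievable = exc.closest
            state = solve_distribution(
                DistributionProblem(
                    moment_arm_matrix=problem.moment_arm_matrix,
                    f_min=lo,
                    f_max=hi,
                    demand=TorqueDemand(float(achievable[0]), float(achievable[1])),
                    active=active,
                    criterion=crit,
                ),
                warm_start=lam,
            )
            tau = achievable
        lam = state.dual

        postures[i] = theta
        demands[i] = tau
        forces[i, active_idx] = state.forces
        tracking[i] = float(np.linalg.norm(target[i] - theta))
        if tracking[i] > _DIVERGENCE_DEG:
            raise DivergenceError(
                f"tracking error {tracking[i]:.1f} deg at t = {trajectory.times[i]:.3f} s "
                f"exceeds {_DIVERGENCE_DEG} deg (kp = {kp}, kd = {kd})"
            )
        if not quasi and i + 1 < n:
            R_now = problem.moment_arm_matrix
            tau_muscle = R_now @ state.forces
            acc = _NMM_PER_KGMM2 * (tau_muscle + tau_g - damping * (vel * deg2rad)) / inertia
            vel = vel + dt * acc / deg2rad
            theta = theta + dt * vel

    cond = condition if condition is not None else ("apl_ablated" if "APL" in config.ablation else "intact")
    result = SimulationResult(
        motion=trajectory.motion,
        specimen_id=specimen.id,
        condition=cond,
        times=trajectory.times.copy(),
        postures=postures,
        target_postures=target,
        torque_demands=demands,
        forces=forces,
        tracking_error=tracking,
        infeasible_steps=infeasible,
        cycle_boundaries=trajectory.cycle_boundaries,
        dt=dt,
        metadata={
            "mode": config.mode,
            "criterion": config.criterion,
            "moment_arm_source": moment_arm_source,
            "ablation": sorted(config.ablation),
            "kp_nmm_per_rad": kp.tolist(),
            "kd_nmm_s_per_rad": kd.tolist(),
            "transient_cycles_discarded": 1,
        },
    )
    result.metadata["rms_tracking_error_deg"] = result.rms_tracking_error()
    if infeasible > 0.01 * n:
        result.metadata["warning"] = (
            f"{infeasible} of {n} steps ({100 * infeasible / n:.1f}%) were infeasible "
            "and fell back to the closest achievable torque"
        )
    return result
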