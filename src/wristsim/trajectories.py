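"""Cyclic wrist motion trajectories.

Four named motions are generated as smooth closed curves in joint-angle
space (degrees; flexion and radial deviation positive):

* ``FE5030``  - planar flexion-extension, 50 deg flexion to 30 deg extension:
  theta_fe(t) = 10 + 40 cos(2 pi t / T), theta_rud = 0.
* ``RUD15``   - planar radioulnar deviation, 15 deg ulnar to 15 deg radial:
  theta_rud(t) = -15 cos(2 pi t / T), theta_fe = 0.
* ``CCD_CW``  - clockwise circumduction: the ellipse
  (theta_fe, theta_rud) = (30 cos phi, -10 sin phi), i.e. 30 flexion ->
  10 ulnar -> 30 extension -> 10 radial.
* ``CCD_ACW`` - anticlockwise circumduction: (30 cos phi, +10 sin phi),
  i.e. 30 flexion -> 10 radial -> 30 extension -> 10 ulnar.

Only the waypoints of each motion are prescribed by the protocol; the
sinusoid/ellipse parameterization is this package's choice so that torque
demands stay continuous. Velocities and accelerations are provided
analytically for feedforward use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputValidationError

__all__ = ["Motion", "Posture", "Trajectory", "GridPoint", "generate_trajectory", "angle_grid"]


class Motion(str, Enum):
    FE5030 = "FE5030"
    RUD15 = "RUD15"
    CCD_CW = "CCD_CW"
    CCD_ACW = "CCD_ACW"


@dataclass(frozen=True)
class Posture:
    """Wrist posture in degrees: flexion positive, radial deviation positive."""

    theta_fe: float
    theta_rud: float

    def __post_init__(self):
        if abs(self.theta_fe) > 90 or abs(self.theta_rud) > 45:
            raise InputValidationError(
                f"posture ({self.theta_fe}, {self.theta_rud}) outside the sanity envelope "
                "(|FE| <= 90 deg, |RUD| <= 45 deg)"
            )


@dataclass(frozen=True)
class GridPoint:
    """One evaluation angle of a motion's analysis grid.

    ``axis`` is the angle being gridded ('FE' or 'RUD'); ``limb`` tags the
    traversal direction for circumduction FE values that are crossed twice
    per cycle ('inc' = FE increasing, 'dec' = FE decreasing, None = single
    pass or planar motion).
    """

    axis: str
    value_deg: float
    limb: str | None = None

    @property
    def label(self) -> str:
        limb = f":{self.limb}" if self.limb else ""
        return f"{self.axis}{self.value_deg:+g}{limb}"


@dataclass(frozen=True)
class Trajectory:
    """Timed sequence of two-axis target postures for one motion.

    Arrays are aligned: ``times`` (s), ``theta_fe``/``theta_rud`` (deg),
    analytic ``omega_*`` (deg/s) and ``alpha_*`` (deg/s^2).
    ``cycle_boundaries[k]`` is the sample index starting cycle k; the final
    sample repeats the initial posture (cyclic closure).
    """

    motion: Motion
    dt: float
    period: float
    cycles: int
    times: np.ndarray
    theta_fe: np.ndarray
    theta_rud: np.ndarray
    omega_fe: np.ndarray
    omega_rud: np.ndarray
    alpha_fe: np.ndarray
    alpha_rud: np.ndarray
    cycle_boundaries: tuple[int, ...] = field(default=())

    def __len__(self):
        return self.times.size

    def posture(self, i: int) -> Posture:
        return Posture(float(self.theta_fe[i]), float(self.theta_rud[i]))

    def to_frame(self) -> pd.DataFrame:
        n_per_cycle = self.cycle_boundaries[1] - self.cycle_boundaries[0]
        cycle_index = np.minimum(np.arange(len(self)) // n_per_cycle, self.cycles - 1)
        return pd.DataFrame(
            {
                "t": self.times,
                "theta_fe_deg": self.theta_fe,
                "theta_rud_deg": self.theta_rud,
                "cycle_index": cycle_index,
            }
        )


_AMPL = {
    # motion -> (fe_offset, fe_amplitude, rud_amplitude_signed)
    Motion.FE5030: (10.0, 40.0, 0.0),
    Motion.RUD15: (0.0, 0.0, -15.0),
    Motion.CCD_CW: (0.0, 30.0, -10.0),
    Motion.CCD_ACW: (0.0, 30.0, +10.0),
}


def generate_trajectory(
    motion: Motion | str, cycles: int = 5, period: float = 4.0, dt: float = 0.0045
) -> Trajectory:
    """Generate a cyclic trajectory of the named motion.

    ``dt`` is adjusted to the nearest value dividing the period exactly so
    every cycle closes on the starting posture to machine precision.
    """
    try:
        motion = Motion(motion)
    except ValueError:
        raise ConfigurationError(f"unknown motion {motion!r}") from None
    if cycles < 1:
        raise ConfigurationError(f"cycles must be >= 1, got {cycles}")
    if not (0 < dt <= period / 100):
        raise ConfigurationError(
            f"dt must satisfy 0 < dt <= period/100 = {period / 100:.6g} s, got {dt}"
        )
    # Round the per-cycle step count to a multiple of 4 so the phase hits
    # 0, pi/2, pi, 3pi/2 exactly: every waypoint extremum is sampled.
    n_per_cycle = 4 * max(int(round(period / dt / 4)), 25)
    dt_eff = period / n_per_cycle
    n = n_per_cycle * cycles + 1  # inclusive endpoint for closure checks
    times = np.arange(n) * dt_eff
    phi = 2 * np.pi * (np.arange(n) % n_per_cycle) / n_per_cycle
    w = 2 * np.pi / period  # rad/s phase rate

    fe0, fe_a, rud_a = _AMPL[motion]
    if motion in (Motion.FE5030, Motion.RUD15):
        theta_fe = fe0 + fe_a * np.cos(phi)
        theta_rud = rud_a * np.cos(phi)
        omega_fe = -fe_a * w * np.sin(phi)
        omega_rud = -rud_a * w * np.sin(phi)
        alpha_fe = -fe_a * w * w * np.cos(phi)
        alpha_rud = -rud_a * w * w * np.cos(phi)
    else:
        theta_fe = fe_a * np.cos(phi)
        theta_rud = rud_a * np.sin(phi)
        omega_fe = -fe_a * w * np.sin(phi)
        omega_rud = rud_a * w * np.cos(phi)
        alpha_fe = -fe_a * w * w * np.cos(phi)
        alpha_rud = -rud_a * w * w * np.sin(phi)

    boundaries = tuple(range(0, n, n_per_cycle))
    return Trajectory(
        motion=motion,
        dt=dt_eff,
        period=period,
        cycles=cycles,
        times=times,
        theta_fe=theta_fe,
        theta_rud=theta_rud,
        omega_fe=omega_fe,
        omega_rud=omega_rud,
        alpha_fe=alpha_fe,
        alpha_rud=alpha_rud,
        cycle_boundaries=boundaries,
    )


def angle_grid(motion: Motion | str) -> list[GridPoint]:
    """Evaluation grid of a motion: every 10 deg in FE and 5 deg in RUD.

    Planar motions grid their moving angle over its full span. For
    circumduction, interior FE values are tagged by traversal limb (they are
    crossed twice per cycle) and the two RUD extrema are added.
    """
    try:
        motion = Motion(motion)
    except ValueError:
        raise ConfigurationError(f"unknown motion {motion!r}") from None
    if motion is Motion.FE5030:
        return [GridPoint("FE", float(v)) for v in range(-30, 51, 10)]
    if motion is Motion.RUD15:
        return [GridPoint("RUD", float(v)) for v in range(-15, 16, 5)]
    pts: list[GridPoint] = [GridPoint("FE", -30.0)]
    for v in range(-20, 21, 10):
        pts.append(GridPoint("FE", float(v), "inc"))
        pts.append(GridPoint("FE", float(v), "dec"))
    pts.append(GridPoint("FE", 30.0))
    rud_extreme = 10.0
    pts.append(GridPoint("RUD", +rud_extreme))
    pts.append(GridPoint("RUD", -rud_extreme))
    return pts
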