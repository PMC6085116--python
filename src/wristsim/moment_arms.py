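"""Passive tendon-excursion moment-arm estimation.

The tendon-excursion method estimates a muscle's moment arm r(theta) about a
joint axis from the tendon displacement E(theta) recorded while the joint is
rotated passively: r = dE/dtheta. With angles in radians and excursions in
millimetres the derivative is directly a moment arm in millimetres.

This module provides (a) a synthetic excursion recorder that integrates a
specimen's true moment-arm polynomial and adds Gaussian measurement noise,
and (b) a least-squares polynomial estimator whose analytic derivative is
the moment-arm fit the controller consumes in "estimated" mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputValidationError, InsufficientDataError, LookupError_
from .specimens import MUSCLES, Specimen

__all__ = [
    "ExcursionRecord",
    "MomentArmFit",
    "simulate_excursion",
    "estimate_moment_arm",
    "estimate_specimen_moment_arms",
]

AXES = ("FE", "RUD")


@dataclass(frozen=True)
class ExcursionRecord:
    """Angle-excursion samples for one (muscle, axis).

    ``angles`` are strictly increasing joint angles in radians; ``excursions``
    are tendon excursions in mm, positive when the tendon shortens toward its
    muscle as the joint moves in the axis-positive direction. ``noise_sigma``
    is metadata recording the simulated measurement noise (mm).
    """

    muscle: str
    axis: str
    angles: np.ndarray
    excursions: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "excursions", np.asarray(self.excursions, dtype=float))
        if self.axis not in AXES:
            raise InputValidationError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.angles.ndim != 1 or self.angles.shape != self.excursions.shape:
            raise InputValidationError("angles and excursions must be matched 1-D arrays")
        if self.angles.size < 3:
            raise InputValidationError("need at least 3 angle-excursion samples")
        if not np.all(np.diff(self.angles) > 0):
            raise InputValidationError("angles must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "muscle": self.muscle,
                "axis": self.axis,
                "angle_deg": np.degrees(self.angles),
                "excursion_mm": self.excursions,
            }
        )


@dataclass(frozen=True)
class MomentArmFit:
    """Polynomial moment-arm estimate r(theta).

    ``coefficients`` are ascending-order coefficients (mm, argument in
    radians) of the analytic derivative of the fitted excursion polynomial;
    ``rmse`` is the residual of the excursion fit itself (mm).
    """

    coefficients: tuple[float, ...]
    fit_degree: int
    rmse: float

    def __call__(self, theta_rad):
        out = 0.0
        for c in reversed(self.coefficients):
            out = out * theta_rad + c
        return out


def simulate_excursion(
    specimen: Specimen,
    muscle: str,
    axis: str,
    angle_grid,
    noise_sigma: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> ExcursionRecord:
    """Record a synthetic passive tendon-excursion trial.

    The noiseless excursion is the analytic integral of the specimen's true
    moment-arm polynomial over the angle grid, anchored to zero at the first
    angle; i.i.d. Gaussian noise of sd ``noise_sigma`` (mm) is then added.
    """
    if muscle not in MUSCLES:
        raise LookupError_(f"unknown muscle {muscle!r}")
    if axis not in AXES:
        raise LookupError_(f"unknown axis {axis!r}")
    angles = np.asarray(angle_grid, dtype=float)
    if angles.ndim != 1 or angles.size < 3 or not np.all(np.diff(angles) > 0):
        raise InputValidationError("angle_grid must be strictly increasing with >= 3 points")
    spec = specimen.muscle(muscle)
    coeffs = spec.ma_fe if axis == "FE" else spec.ma_rud
    # antiderivative of the ascending-order polynomial
    anti = np.polynomial.Polynomial(coeffs).integ()
    excursions = anti(angles) - anti(angles[0])
    if noise_sigma < 0:
        raise InputValidationError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        excursions = excursions + rng.normal(0.0, noise_sigma, size=angles.size)
    return ExcursionRecord(
        muscle=muscle, axis=axis, angles=angles, excursions=excursions, noise_sigma=noise_sigma
    )


def estimate_moment_arm(record: ExcursionRecord, fit_degree: int = 2) -> MomentArmFit:
    """Least-squares polynomial fit of excursion vs angle, differentiated.

    Fits E(theta) with a polynomial of the given degree and returns its
    analytic derivative as the moment-arm polynomial (degree - 1). The RMSE
    is reported on the excursion residuals (mm).
    """
    if fit_degree < 1:
        raise InputValidationError(f"fit_degree must be >= 1, got {fit_degree}")
    n = record.angles.size
    if n <= fit_degree + 1:
        raise InsufficientDataError(
            f"need more than fit_degree + 1 = {fit_degree + 1} points, got {n}"
        )
    # Fit in a scaled domain for conditioning, then convert back to plain
    # power-series coefficients in radians.
    p = np.polynomial.Polynomial.fit(record.angles, record.excursions, deg=fit_degree)
    resid = record.excursions - p(record.angles)
    rmse = float(np.sqrt(np.mean(resid**2)))
    deriv = p.deriv().convert()
    coeffs = tuple(float(c) for c in deriv.coef)
    return MomentArmFit(coefficients=coeffs, fit_degree=int(fit_degree), rmse=rmse)


def estimate_specimen_moment_arms(
    specimen: Specimen,
    fit_degree: int = 2,
    n_points: int = 25,
    noise_sigma: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    fe_range_deg: tuple[float, float] = (-35.0, 55.0),
    rud_range_deg: tuple[float, float] = (-20.0, 20.0),
) -> dict[tuple[str, str], MomentArmFit]:
    """Run passive excursion trials for all (muscle, axis) pairs and fit them.

    Returns a dict keyed by (muscle, axis). Each trial uses its own child
    random stream of ``seed`` so results are independent of iteration order.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    children = iter(ss.spawn(len(MUSCLES) * len(AXES)))
    fits: dict[tuple[str, str], MomentArmFit] = {}
    for muscle in MUSCLES:
        for axis in AXES:
            lo, hi = fe_range_deg if axis == "FE" else rud_range_deg
            grid = np.radians(np.linspace(lo, hi, n_points))
            rec = simulate_excursion(
                specimen, muscle, axis, grid, noise_sigma=noise_sigma, seed=next(children)
            )
            fits[(muscle, axis)] = estimate_moment_arm(rec, fit_degree=fit_degree)
    return fits
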