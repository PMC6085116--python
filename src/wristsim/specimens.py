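"""Synthetic wrist specimens.

A *specimen* is a parameterized stand-in for one cadaveric arm mounted on a
physiological wrist simulator: six muscles (FCR, FCU, ECRL, ECRB, ECU, APL)
with signed moment arms about the flexion-extension (FE) and radioulnar-
deviation (RUD) axes, PCSA-derived force bounds, and the inertial parameters
of the hand segment.

Sign conventions (fixed package-wide):

* flexion torque is positive about the FE axis,
* radial-deviation torque is positive about the RUD axis.

So a flexor has ``ma_fe > 0`` at neutral and a radial deviator has
``ma_rud > 0`` at neutral. The six muscles realize the following role table
at the neutral posture, which the generator preserves under any random
perturbation::

    FCR  (+, +)   flexor, weak radial deviator
    FCU  (+, -)   flexor, ulnar deviator
    ECRL (-, +)   extensor, radial deviator
    ECRB (-, +)   extensor, weak radial deviator
    ECU  (-, -)   extensor, ulnar deviator
    APL  (+, +)   weak flexor, strong radial deviator

Moment arms are stored as polynomials in the same-axis joint angle
(radians), ascending-order coefficients in millimetres; the default cohort
uses constant (degree-0) moment arms.

Default cohort means are literature-scale placeholder values chosen to be
consistent with the role table above; they are configuration entries, not
measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputValidationError, LookupError_

__all__ = [
    "MUSCLES",
    "ROLE_SIGNS",
    "MuscleSpec",
    "Specimen",
    "CohortParams",
    "make_specimen",
    "make_cohort",
    "cohort_manifest",
]

#: Canonical muscle ordering used everywhere (force vectors, matrices, CSV).
MUSCLES: tuple[str, ...] = ("FCR", "FCU", "ECRL", "ECRB", "ECU", "APL")

#: Required sign of (ma_fe, ma_rud) at the neutral posture for each muscle.
ROLE_SIGNS: dict[str, tuple[int, int]] = {
    "FCR": (+1, +1),
    "FCU": (+1, -1),
    "ECRL": (-1, +1),
    "ECRB": (-1, +1),
    "ECU": (-1, -1),
    "APL": (+1, +1),
}

# Placeholder cohort means (cm^2 and mm); configurable via CohortParams.
_DEFAULT_PCSA = {"FCR": 2.0, "FCU": 3.4, "ECRL": 2.4, "ECRB": 2.9, "ECU": 3.4, "APL": 1.9}
_DEFAULT_NEUTRAL_MA = {
    "FCR": (10.0, 4.0),
    "FCU": (12.0, -14.0),
    "ECRL": (-7.0, 13.0),
    "ECRB": (-12.0, 6.0),
    "ECU": (-6.0, -17.0),
    "APL": (4.0, 19.0),
}


def _polyval(coeffs: Sequence[float], x: float | np.ndarray):
    """Evaluate an ascending-order polynomial."""
    out = 0.0
    for c in reversed(coeffs):
        out = out * x + c
    return out


@dataclass(frozen=True)
class MuscleSpec:
    """One muscle's moment-arm polynomials, PCSA, and force bounds.

    Parameters
    ----------
    name : str
        One of :data:`MUSCLES`.
    pcsa : float
        Physiological cross-sectional area, cm^2; must be positive.
    specific_tension : float
        Maximum isometric stress, N/cm^2; must be positive.
    min_activity : float
        Minimum tonic activity as a fraction of maximum force, in [0, 1).
        Models the EMG-derived minimum tension kept on each tendon.
    ma_fe, ma_rud : tuple of float
        Ascending polynomial coefficients (mm) of the moment arm about the
        FE / RUD axis as a function of the same-axis angle in radians.
    """

    name: str
    pcsa: float
    specific_tension: float
    min_activity: float
    ma_fe: tuple[float, ...]
    ma_rud: tuple[float, ...]

    def __post_init__(self):
        if self.name not in MUSCLES:
            raise InputValidationError(f"unknown muscle name {self.name!r}")
        if not self.pcsa > 0:
            raise InputValidationError(f"{self.name}: pcsa must be > 0, got {self.pcsa}")
        if not self.specific_tension > 0:
            raise InputValidationError(
                f"{self.name}: specific_tension must be > 0, got {self.specific_tension}"
            )
        if not (0 <= self.min_activity < 1):
            raise InputValidationError(
                f"{self.name}: min_activity must be in [0, 1), got {self.min_activity}"
            )
        for attr in ("ma_fe", "ma_rud"):
            coeffs = getattr(self, attr)
            if len(coeffs) < 1:
                raise InputValidationError(f"{self.name}: {attr} needs >= 1 coefficient")
            object.__setattr__(self, attr, tuple(float(c) for c in coeffs))

    @property
    def f_max(self) -> float:
        """Upper force bound: PCSA x specific tension (N)."""
        return self.pcsa * self.specific_tension

    @property
    def f_min(self) -> float:
        """Lower force bound: minimum tonic activity x F_max (N)."""
        return self.min_activity * self.f_max

    def moment_arm_fe(self, theta_fe_rad: float | np.ndarray):
        """Moment arm about the FE axis (mm) at the given FE angle (rad)."""
        return _polyval(self.ma_fe, theta_fe_rad)

    def moment_arm_rud(self, theta_rud_rad: float | np.ndarray):
        """Moment arm about the RUD axis (mm) at the given RUD angle (rad)."""
        return _polyval(self.ma_rud, theta_rud_rad)


@dataclass(frozen=True)
class Specimen:
    """A complete six-muscle wrist instance plus hand segment parameters.

    Hand inertial parameters use kg and mm: ``hand_mass`` (kg),
    ``hand_com_distance`` (mm from the wrist axes to the hand centre of
    mass), principal rotational inertias (kg*mm^2) and viscous damping
    coefficients (N*mm*s/rad) about each axis.
    """

    id: str
    muscles: Mapping[str, MuscleSpec]
    hand_mass: float = 0.45
    hand_com_distance: float = 60.0
    hand_inertia_fe: float = 1620.0
    hand_inertia_rud: float = 1620.0
    damping_fe: float = 5.0
    damping_rud: float = 5.0

    def __post_init__(self):
        if set(self.muscles) != set(MUSCLES):
            raise InputValidationError(
                f"specimen {self.id}: needs exactly one MuscleSpec per muscle in {MUSCLES}"
            )
        object.__setattr__(self, "muscles", {m: self.muscles[m] for m in MUSCLES})
        for attr in (
            "hand_mass",
            "hand_com_distance",
            "hand_inertia_fe",
            "hand_inertia_rud",
            "damping_fe",
            "damping_rud",
        ):
            if not getattr(self, attr) > 0:
                raise InputValidationError(
                    f"specimen {self.id}: {attr} must be > 0, got {getattr(self, attr)}"
                )
        for name, spec in self.muscles.items():
            s_fe, s_rud = ROLE_SIGNS[name]
            if np.sign(spec.moment_arm_fe(0.0)) != s_fe or np.sign(spec.moment_arm_rud(0.0)) != s_rud:
                raise InputValidationError(
                    f"specimen {self.id}: {name} neutral moment-arm signs violate the role table"
                )

    def muscle(self, name: str) -> MuscleSpec:
        try:
            return self.muscles[name]
        except KeyError:
            raise LookupError_(f"specimen {self.id} has no muscle {name!r}") from None

    def moment_arm_matrix(
        self, theta_fe_rad: float, theta_rud_rad: float, order: Sequence[str] = MUSCLES
    ) -> np.ndarray:
        """2 x m moment-arm matrix (mm): row 0 = FE, row 1 = RUD."""
        R = np.empty((2, len(order)))
        for j, name in enumerate(order):
            spec = self.muscle(name)
            R[0, j] = spec.moment_arm_fe(theta_fe_rad)
            R[1, j] = spec.moment_arm_rud(theta_rud_rad)
        return R

    def f_bounds(self, order: Sequence[str] = MUSCLES) -> tuple[np.ndarray, np.ndarray]:
        """(f_min, f_max) arrays (N) in the given muscle order."""
        lo = np.array([self.muscle(m).f_min for m in order])
        hi = np.array([self.muscle(m).f_max for m in order])
        return lo, hi

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "hand_mass": self.hand_mass,
            "hand_com_distance": self.hand_com_distance,
            "hand_inertia_fe": self.hand_inertia_fe,
            "hand_inertia_rud": self.hand_inertia_rud,
            "damping_fe": self.damping_fe,
            "damping_rud": self.damping_rud,
            "muscles": {
                m: {
                    "name": s.name,
                    "pcsa": s.pcsa,
                    "specific_tension": s.specific_tension,
                    "min_activity": s.min_activity,
                    "ma_fe": list(s.ma_fe),
                    "ma_rud": list(s.ma_rud),
                }
                for m, s in self.muscles.items()
            },
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "Specimen":
        muscles = {
            m: MuscleSpec(
                name=spec["name"],
                pcsa=spec["pcsa"],
                specific_tension=spec["specific_tension"],
                min_activity=spec["min_activity"],
                ma_fe=tuple(spec["ma_fe"]),
                ma_rud=tuple(spec["ma_rud"]),
            )
            for m, spec in d["muscles"].items()
        }
        kwargs = {k: d[k] for k in d if k not in ("muscles",)}
        return cls(muscles=muscles, **kwargs)

    @classmethod
    def from_json(cls, text_or_path) -> "Specimen":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class CohortParams:
    """Distribution settings for the synthetic cohort generator.

    ``pcsa_mean`` (cm^2) and ``neutral_ma_mean`` (mm, (FE, RUD) pairs) give
    the cohort means; ``cv`` is the coefficient of variation of the
    log-normal multiplicative scatter applied independently to each PCSA and
    each neutral moment-arm magnitude. Moment-arm signs are never perturbed,
    so the role table holds for every generated specimen.
    """

    pcsa_mean: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PCSA))
    neutral_ma_mean: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_NEUTRAL_MA)
    )
    specific_tension: float = 35.0
    min_activity: float = 0.025
    cv: float = 0.15
    hand_mass: float = 0.45
    hand_com_distance: float = 60.0
    hand_inertia: float = 1620.0
    damping: float = 5.0

    def __post_init__(self):
        if self.cv < 0:
            raise ConfigurationError(f"cv must be >= 0, got {self.cv}")
        if not self.specific_tension > 0:
            raise ConfigurationError("specific_tension must be > 0")
        if not (0 <= self.min_activity < 1):
            raise ConfigurationError("min_activity must be in [0, 1)")
        if set(self.pcsa_mean) != set(MUSCLES) or set(self.neutral_ma_mean) != set(MUSCLES):
            raise ConfigurationError(f"pcsa_mean and neutral_ma_mean must cover {MUSCLES}")
        for m in MUSCLES:
            if not self.pcsa_mean[m] > 0:
                raise ConfigurationError(f"pcsa_mean[{m}] must be > 0")
            fe, rud = self.neutral_ma_mean[m]
            s_fe, s_rud = ROLE_SIGNS[m]
            if np.sign(fe) != s_fe or np.sign(rud) != s_rud or fe == 0 or rud == 0:
                raise ConfigurationError(
                    f"neutral_ma_mean[{m}] = {(fe, rud)} violates the role-sign table"
                )
        for attr in ("hand_mass", "hand_com_distance", "hand_inertia", "damping"):
            if not getattr(self, attr) > 0:
                raise ConfigurationError(f"{attr} must be > 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative scatter with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def make_specimen(
    seed: int | np.random.SeedSequence,
    cohort_params: CohortParams | None = None,
    specimen_id: str | None = None,
) -> Specimen:
    """Generate one synthetic specimen, a pure function of (seed, params).

    PCSA and neutral moment-arm magnitudes receive independent log-normal
    multiplicative noise with the configured CV; signs are taken from the
    cohort means, so the neutral role table is satisfied by construction.
    """
    params = cohort_params if cohort_params is not None else CohortParams()
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        seed = int(seed)
        if seed < 0:
            raise ConfigurationError(f"seed must be non-negative, got {seed}")
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    muscles = {}
    for m in MUSCLES:
        pcsa = params.pcsa_mean[m] * _lognormal_factor(rng, params.cv)
        fe_mean, rud_mean = params.neutral_ma_mean[m]
        ma_fe = abs(fe_mean) * _lognormal_factor(rng, params.cv) * np.sign(fe_mean)
        ma_rud = abs(rud_mean) * _lognormal_factor(rng, params.cv) * np.sign(rud_mean)
        muscles[m] = MuscleSpec(
            name=m,
            pcsa=float(pcsa),
            specific_tension=params.specific_tension,
            min_activity=params.min_activity,
            ma_fe=(float(ma_fe),),
            ma_rud=(float(ma_rud),),
        )
    return Specimen(
        id=specimen_id if specimen_id is not None else f"specimen_{ss.entropy}",
        muscles=muscles,
        hand_mass=params.hand_mass,
        hand_com_distance=params.hand_com_distance,
        hand_inertia_fe=params.hand_inertia,
        hand_inertia_rud=params.hand_inertia,
        damping_fe=params.damping,
        damping_rud=params.damping,
    )


def make_cohort(
    n: int, base_seed: int, cohort_params: CohortParams | None = None
) -> list[Specimen]:
    """Generate ``n`` specimens, ids ``specimen_1 .. specimen_n``.

    Each specimen draws from its own child random stream of ``base_seed``,
    so enlarging the cohort never reshuffles earlier specimens.
    """
    if n < 1:
        raise ConfigurationError(f"cohort size must be >= 1, got {n}")
    children = np.random.SeedSequence(int(base_seed)).spawn(int(n))
    return [
        make_specimen(child, cohort_params, specimen_id=f"specimen_{i + 1}")
        for i, child in enumerate(children)
    ]


def cohort_manifest(cohort: Iterable[Specimen]) -> pd.DataFrame:
    """One row per (specimen, muscle): PCSA, bounds, neutral moment arms."""
    rows = []
    for spec in cohort:
        for m in MUSCLES:
            mu = spec.muscle(m)
            rows.append(
                {
                    "specimen": spec.id,
                    "muscle": m,
                    "pcsa_cm2": mu.pcsa,
                    "f_min_N": mu.f_min,
                    "f_max_N": mu.f_max,
                    "ma_fe_neutral_mm": mu.moment_arm_fe(0.0),
                    "ma_rud_neutral_mm": mu.moment_arm_rud(0.0),
                }
            )
    return pd.DataFrame(rows)
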