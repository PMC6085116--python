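"""Redundant muscle force distribution (static optimization).

The wrist has two controlled axes and up to six muscles, so realizing a
torque demand tau = (tau_FE, tau_RUD) leaves a four-parameter family of
muscle-force vectors. This module resolves the redundancy by static
optimization: minimize a separable, strictly convex effort criterion

    J(f) = sum_i (f_i / F_max,i)^2            (normalized effort, default)
or  J(f) = sum_i (f_i / PCSA_i)^3             (summed cubed muscle stress)

subject to R f = tau and per-muscle bounds f_min <= f <= f_max, where R is
the 2 x m moment-arm matrix (mm) and forces are in N, torques in N*mm.

The solver maximizes the two-dimensional dual: for multipliers lam in R^2
the box-constrained minimizer is f_i(lam) = clip(h_i((R^T lam)_i)), with
h_i the inverse of the criterion's marginal cost, and the dual residual
R f(lam) - tau is driven to zero with a damped (semismooth) Newton
iteration. A sequential-quadratic-programming polish is kept as a fallback
for the rare instance on which Newton stalls. Demands outside the
achievable torque set (a zonotope) raise an error carrying the closest
achievable torque.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import lsq_linear, minimize

from .errors import InfeasibleTorqueError, InputValidationError

__all__ = [
    "TorqueDemand",
    "DistributionProblem",
    "ForceState",
    "EffortCriterion",
    "NormalizedEffort",
    "CubedStress",
    "make_criterion",
    "solve_distribution",
    "feasible_torque_set",
    "contains_torque",
    "closest_torque",
]

_RESIDUAL_TOL = 1e-9  # internal Newton target, relative to max(1, |tau|)
_FEASIBLE_TOL = 1e-6  # feasibility verdict threshold, same scaling


@dataclass(frozen=True)
class TorqueDemand:
    """Two-axis torque demand in N*mm (flexion and radial deviation positive)."""

    tau_fe: float
    tau_rud: float

    def __post_init__(self):
        if not (np.isfinite(self.tau_fe) and np.isfinite(self.tau_rud)):
            raise InputValidationError("torque demand must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.tau_fe, self.tau_rud])


class EffortCriterion:
    """Separable strictly convex effort criterion.

    Subclasses supply the cost, the inverse marginal cost ``h`` (the
    unconstrained minimizer of ``c_i(f) - g f`` for marginal price g), and
    its derivative ``h_prime`` used in the dual Newton step.
    """

    name: str = "abstract"

    def cost(self, f: np.ndarray) -> float:
        raise NotImplementedError

    def grad(self, f: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def h(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def h_prime(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class NormalizedEffort(EffortCriterion):
    """sum (f_i / F_max,i)^2 - the standard normalized-effort criterion."""

    name = "normalized_quadratic"

    def __init__(self, f_max: np.ndarray):
        self.f_max = np.asarray(f_max, dtype=float)
        self._w = self.f_max**2 / 2.0

    def cost(self, f):
        return float(np.sum((f / self.f_max) ** 2))

    def grad(self, f):
        return 2.0 * f / self.f_max**2

    def h(self, g):
        return self._w * g

    def h_prime(self, g):
        return np.broadcast_to(self._w, np.shape(g)).copy()


class CubedStress(EffortCriterion):
    """sum (f_i / PCSA_i)^3 - summed cubed muscle stress (f >= 0)."""

    name = "cubed_stress"

    def __init__(self, pcsa: np.ndarray):
        self.pcsa = np.asarray(pcsa, dtype=float)
        self._p3 = self.pcsa**3

    def cost(self, f):
        return float(np.sum((np.maximum(f, 0.0) / self.pcsa) ** 3))

    def grad(self, f):
        return 3.0 * np.maximum(f, 0.0) ** 2 / self._p3

    def h(self, g):
        g = np.maximum(g, 0.0)
        return np.sqrt(g * self._p3 / 3.0)

    def h_prime(self, g):
        gp = np.maximum(g, 1e-300)
        return 0.5 * np.sqrt(self._p3 / (3.0 * gp))


def make_criterion(name: str, f_max: np.ndarray, pcsa: np.ndarray | None = None) -> EffortCriterion:
    if name == NormalizedEffort.name:
        return NormalizedEffort(f_max)
    if name == CubedStress.name:
        if pcsa is None:
            raise InputValidationError("cubed_stress criterion requires PCSA values")
        return CubedStress(pcsa)
    raise InputValidationError(f"unknown effort criterion {name!r}")


@dataclass
class DistributionProblem:
    """One static force-distribution instance.

    ``moment_arm_matrix`` is 2 x m (mm), rows (FE, RUD), columns the active
    muscles in ``active`` order; ``f_min``/``f_max`` are N. ``criterion``
    defaults to normalized effort with the problem's own upper bounds.
    """

    moment_arm_matrix: np.ndarray
    f_min: np.ndarray
    f_max: np.ndarray
    demand: TorqueDemand
    active: tuple[str, ...] = ()
    criterion: EffortCriterion | None = None
    pcsa: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.moment_arm_matrix = np.atleast_2d(np.asarray(self.moment_arm_matrix, dtype=float))
        self.f_min = np.asarray(self.f_min, dtype=float)
        self.f_max = np.asarray(self.f_max, dtype=float)
        R = self.moment_arm_matrix
        m = R.shape[1]
        if R.shape[0] != 2 or m < 1:
            raise InputValidationError(f"moment-arm matrix must be 2 x m with m >= 1, got {R.shape}")
        if self.f_min.shape != (m,) or self.f_max.shape != (m,):
            raise InputValidationError("f_min/f_max must have one entry per active muscle")
        if np.any(self.f_min < 0) or np.any(self.f_min >= self.f_max):
            raise InputValidationError("bounds must satisfy 0 <= f_min < f_max per muscle")
        if np.any(np.all(R == 0.0, axis=0)):
            raise InputValidationError("moment-arm matrix has an all-zero column")
        if not self.active:
            self.active = tuple(f"m{j}" for j in range(m))
        if self.criterion is None:
            self.criterion = NormalizedEffort(self.f_max)

    @property
    def m(self) -> int:
        return self.moment_arm_matrix.shape[1]


@dataclass(frozen=True)
class ForceState:
    """Solver output: per-muscle tensions (N) for the problem's active set."""

    forces: np.ndarray
    cost: float
    feasible: bool
    residual: float
    dual: np.ndarray = field(default=None, repr=False)


def _newton_dual(R, lo, hi, tau, crit, lam0, tol, max_iter=100):
    """Damped semismooth Newton on the dual residual R f(lam) - tau."""
    lam = np.array(lam0, dtype=float)
    g = R.T @ lam
    f = np.clip(crit.h(g), lo, hi)
    phi = R @ f - tau
    norm = np.linalg.norm(phi)
    scale = float(np.max(np.abs(R) * np.maximum(np.abs(hi), 1.0))) + 1.0
    reg = 1e-14 * scale
    for _ in range(max_iter):
        if norm <= tol:
            return lam, f, True
        h_unc = crit.h(g)
        inside = (h_unc > lo) & (h_unc < hi)
        slopes = np.where(inside, crit.h_prime(g), 0.0)
        J = (R * slopes) @ R.T
        J[0, 0] += reg
        J[1, 1] += reg
        try:
            step = np.linalg.solve(J, -phi)
        except np.linalg.LinAlgError:
            reg *= 100.0
            continue
        alpha = 1.0
        accepted = False
        while alpha > 1e-12:
            lam_try = lam + alpha * step
            g_try = R.T @ lam_try
            f_try = np.clip(crit.h(g_try), lo, hi)
            phi_try = R @ f_try - tau
            n_try = np.linalg.norm(phi_try)
            if n_try < norm * (1.0 - 1e-4 * alpha) or n_try <= tol:
                lam, g, f, phi, norm = lam_try, g_try, f_try, phi_try, n_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            reg *= 100.0
            if reg > scale:
                break
    return lam, f, norm <= tol


def _sqp_polish(R, lo, hi, tau, crit, f0):
    cons = {"type": "eq", "fun": lambda f: R @ f - tau, "jac": lambda f: R}
    res = minimize(
        crit.cost,
        np.clip(f0, lo, hi),
        jac=crit.grad,
        bounds=list(zip(lo, hi)),
        constraints=[cons],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    return np.clip(res.x, lo, hi)


def closest_torque(R, f_min, f_max, tau) -> tuple[np.ndarray, np.ndarray]:
    """Bounded least squares: forces realizing the torque closest to tau."""
    res = lsq_linear(R, tau, bounds=(f_min, f_max), tol=1e-14)
    return R @ res.x, res.x


def solve_distribution(
    problem: DistributionProblem,
    warm_start: np.ndarray | None = None,
) -> ForceState:
    """Distribute the torque demand across the active muscles.

    Returns the unique minimizer of the problem's effort criterion subject
    to torque balance and bounds. Raises :class:`InfeasibleTorqueError`
    (carrying the closest achievable torque) when the demand lies outside
    the achievable set.
    """
    R = problem.moment_arm_matrix
    lo, hi = problem.f_min, problem.f_max
    tau = problem.demand.vector
    crit = problem.criterion
    tol = _RESIDUAL_TOL * max(1.0, float(np.max(np.abs(tau))))

    if warm_start is not None:
        lam0 = np.asarray(warm_start, dtype=float)
    else:
        # all-interior least-squares guess for the dual
        slopes = crit.h_prime(np.ones(problem.m))
        J0 = (R * np.maximum(slopes, 1e-12)) @ R.T
        J0[0, 0] += 1e-12
        J0[1, 1] += 1e-12
        try:
            lam0 = np.linalg.solve(J0, tau - R @ lo)
        except np.linalg.LinAlgError:
            lam0 = np.zeros(2)

    lam, f, ok = _newton_dual(R, lo, hi, tau, crit, lam0, tol)
    if not ok and warm_start is not None:
        # retry from the cold-start guess before declaring trouble
        lam, f, ok = _newton_dual(R, lo, hi, tau, crit, np.zeros(2), tol)
    if not ok:
        achievable, f_ls = closest_torque(R, lo, hi, tau)
        feas_tol = _FEASIBLE_TOL * max(1.0, float(np.max(np.abs(tau))))
        if np.linalg.norm(achievable - tau) > feas_tol:
            raise InfeasibleTorqueError(tau, achievable)
        f = _sqp_polish(R, lo, hi, tau, crit, f_ls)
        lam = np.zeros(2)

    residual = float(np.max(np.abs(R @ f - tau)))
    return ForceState(
        forces=f,
        cost=crit.cost(f),
        feasible=True,
        residual=residual,
        dual=lam,
    )


def feasible_torque_set(R, f_min, f_max) -> np.ndarray:
    """Vertices of the achievable torque set {R f : f_min <= f <= f_max}.

    The set is a zonotope: the Minkowski sum of the segments R_i [f_min_i,
    f_max_i] translated by R f_min. Returns its vertices in counterclockwise
    order as an array of shape (k, 2); degenerate sets return a segment
    (k = 2) or a point (k = 1).
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    f_min = np.asarray(f_min, dtype=float)
    f_max = np.asarray(f_max, dtype=float)
    offset = R @ f_min
    gens = (R * (f_max - f_min)).T  # m x 2 generator segments
    scale = float(np.max(np.abs(gens))) if gens.size else 0.0
    gens = gens[np.hypot(gens[:, 0], gens[:, 1]) > 1e-12 * max(scale, 1.0)]
    if gens.shape[0] == 0:
        return offset[None, :]
    # Support-function sampling strictly between consecutive edge normals:
    # each generator contributes an edge whose outward normal is +-90 deg
    # from its direction; midpoint directions select one vertex each.
    normals = []
    for gx, gy in gens:
        a = np.arctan2(gy, gx)
        normals.extend([a + np.pi / 2, a - np.pi / 2])
    normals = np.unique(np.mod(normals, 2 * np.pi))
    mids = np.concatenate([(normals[:-1] + normals[1:]) / 2, [(normals[-1] + normals[0] + 2 * np.pi) / 2]])
    verts = []
    for ang in mids:
        d = np.array([np.cos(ang), np.sin(ang)])
        v = offset + gens[gens @ d > 0].sum(axis=0)
        if not verts or np.linalg.norm(v - verts[-1]) > 1e-9 * max(scale, 1.0):
            verts.append(v)
    verts = np.array(verts)
    if len(verts) > 1 and np.linalg.norm(verts[0] - verts[-1]) <= 1e-9 * max(scale, 1.0):
        verts = verts[:-1]
    # order counterclockwise around the centroid for a canonical output
    c = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
    return verts[order]


def contains_torque(vertices: np.ndarray, tau, tol: float = 1e-7) -> bool:
    """Point-in-convex-polygon test with tolerance (handles degenerate sets)."""
    tau = np.asarray(tau, dtype=float)
    V = np.atleast_2d(vertices)
    scale = max(1.0, float(np.max(np.abs(V))))
    if V.shape[0] == 1:
        return bool(np.linalg.norm(tau - V[0]) <= tol * scale)
    if V.shape[0] == 2:
        a, b = V
        ab = b - a
        t = np.clip(np.dot(tau - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
        return bool(np.linalg.norm(tau - (a + t * ab)) <= tol * scale)
    for i in range(V.shape[0]):
        a = V[i]
        b = V[(i + 1) % V.shape[0]]
        cross = (b[0] - a[0]) * (tau[1] - a[1]) - (b[1] - a[1]) * (tau[0] - a[0])
        if cross < -tol * scale * scale:
            return False
    return True
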