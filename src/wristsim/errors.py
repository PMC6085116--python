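"""Exception hierarchy for wristsim.

All wristsim-specific failures derive from :class:`WristSimError` so callers
can catch the package's errors with a single except clause. Configuration
problems additionally derive from ``ValueError`` for ergonomic use in
validation code.
"""

from __future__ import annotations

import numpy as np


class WristSimError(Exception):
    """Base class for all wristsim errors."""


class ConfigurationError(WristSimError, ValueError):
    """Invalid configuration value (negative CV, zero mean, bad dt, ...)."""


class InputValidationError(WristSimError, ValueError):
    """Structurally invalid input data (non-increasing angles, bad bounds, ...)."""


class InsufficientDataError(WristSimError, ValueError):
    """Too few data points for the requested fit."""


class LookupError_(WristSimError, KeyError):
    """Unknown muscle or axis requested from a specimen."""


class InfeasibleTorqueError(WristSimError):
    """The demanded torque lies outside the achievable torque set.

    Attributes
    ----------
    demand : ndarray, shape (2,)
        The requested (FE, RUD) torque in N*mm.
    closest : ndarray, shape (2,)
        The closest achievable torque (Euclidean projection onto the
        feasible set), usable as a fallback demand.
    """

    def __init__(self, demand, closest):
        self.demand = np.asarray(demand, dtype=float)
        self.closest = np.asarray(closest, dtype=float)
        gap = float(np.linalg.norm(self.demand - self.closest))
        super().__init__(
            f"torque demand {tuple(self.demand)} N*mm is infeasible; "
            f"closest achievable is {tuple(self.closest)} (gap {gap:.3g} N*mm)"
        )


class DivergenceError(WristSimError):
    """Closed-loop tracking diverged (error exceeded the hard limit)."""


class MissingSampleError(WristSimError):
    """A grid angle was never visited within its phase window."""


class PairingError(WristSimError):
    """Intact/ablated runs could not be paired specimen-by-specimen."""


class DegenerateSampleError(WristSimError):
    """All paired differences are zero; the signed-rank test is undefined."""
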