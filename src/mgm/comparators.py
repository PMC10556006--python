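"""Comparator growth models and analytic oracles.

The main reference is the generalized standard growth model (GSGM),

    dW/dt = a*W**b - c*W**d,

the umbrella form behind von Bertalanffy, the ontogenetic growth model
and standard dynamic-energy-budget growth (with ``d = 1`` for the best
match to such models).  Its hump position W*/W_U has the closed form
(b/d)**(1/(d-b)); for d = 1 the supremum over b in (0, 1) is 1/e, a hard
ceiling that sigmoid curves with a later hump simply cannot satisfy —
the analytic reason a defence-allocation term in maintenance is needed
for cricket-like growth.

All comparators register in :data:`MODEL_REGISTRY`, which the fitting
module uses; user-defined rate models can be added via
:func:`register_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

from .exceptions import DomainError, SingularMaintenanceError

__all__ = [
    "GSGMParams",
    "gsgm_rate",
    "gsgm_omega_star",
    "vb_rate",
    "vb_closed_form",
    "vb_time_to_mass",
    "logistic_rate",
    "mgm_reduced_rate",
    "RateModel",
    "MODEL_REGISTRY",
    "register_model",
    "get_model",
]


@dataclass(frozen=True)
class GSGMParams:
    """Parameters of dW/dt = a*W**b - c*W**d (supply minus expenditure)."""

    a: float
    b: float
    c: float
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise DomainError("a and c must be > 0")
        if not 0.0 < self.b < self.d or self.d > 1.0:
            raise DomainError(
                f"bounded growth requires 0 < b < d <= 1, got b={self.b}, d={self.d}"
            )


def gsgm_rate(W: float, p: GSGMParams) -> float:
    """Growth rate of the generalized standard growth model (mg/day)."""
    if W <= 0:
        raise DomainError(f"body mass must be > 0, got {W}")
    return p.a * W**p.b - p.c * W**p.d


def gsgm_omega_star(b: float, d: float = 1.0) -> float:
    """Closed-form hump position W*/W_U of the GSGM.

    Setting the derivative of a*W**b - c*W**d to zero gives
    W* = (a*b/(c*d))**(1/(d-b)) while W_U = (a/c)**(1/(d-b)), so the
    ratio is (b/d)**(1/(d-b)) independently of a and c.  For d = 1 this
    is b**(1/(1-b)), bounded above by 1/e.
    """
    if not 0.0 < b < d:
        raise DomainError(f"need 0 < b < d, got b={b}, d={d}")
    return (b / d) ** (1.0 / (d - b))


def vb_rate(W: float, a: float, b: float, beta: float) -> float:
    """von Bertalanffy-type rate dW/dt = a*W**beta - b*W."""
    if W <= 0:
        raise DomainError(f"body mass must be > 0, got {W}")
    return a * W**beta - b * W


def vb_closed_form(t, a: float, b: float, beta: float, W0: float):
    """Exact solution of dW/dt = a*W**beta - b*W (a Bernoulli equation).

        W(t) = [a/b + (W0**(1-beta) - a/b) * exp(-(1-beta)*b*t)]**(1/(1-beta))

    ``t`` may be a scalar or array.  Raises for beta = 1, where the
    equation degenerates to pure exponential growth/decline and this
    formula does not apply.
    """
    if not 0.0 < beta < 1.0:
        raise DomainError(
            f"closed form requires 0 < beta < 1 (got {beta}); beta = 1 is the "
            "degenerate exponential case W(t) = W0*exp((a-b)*t)"
        )
    if b <= 0:
        raise DomainError(f"b must be > 0, got {b}")
    if W0 <= 0:
        raise DomainError(f"W0 must be > 0, got {W0}")
    t = np.asarray(t, dtype=float)
    k = 1.0 - beta
    core = a / b + (W0**k - a / b) * np.exp(-k * b * t)
    out = core ** (1.0 / k)
    return float(out) if out.ndim == 0 else out


def vb_time_to_mass(W: float, a: float, b: float, beta: float, W0: float) -> float:
    """Inverse of :func:`vb_closed_form`: age at which mass ``W`` is reached."""
    if not 0.0 < beta < 1.0:
        raise DomainError(f"requires 0 < beta < 1, got {beta}")
    k = 1.0 - beta
    Winf_k = a / b
    num = W**k - Winf_k
    den = W0**k - Winf_k
    if num / den <= 0:
        raise DomainError(f"mass {W} is not on the trajectory from W0 = {W0}")
    return -math.log(num / den) / (k * b)


def logistic_rate(W: float, r: float, K: float) -> float:
    """Logistic comparator dW/dt = r*W*(1 - W/K)."""
    if r <= 0 or K <= 0:
        raise DomainError("r and K must be > 0")
    return r * W * (1.0 - W / K)


def mgm_reduced_rate(W: float, a: float, beta: float, c: float, a_N: float) -> float:
    """Reduced ad-libitum maintenance-growth rate with linear defence allometry:

        dW/dt = a*W**beta - c*W / (1 - a_N*W)

    the four-parameter form used for data fitting.  As a_N -> 0 this
    degenerates to the GSGM with d = 1.
    """
    if W <= 0:
        raise DomainError(f"body mass must be > 0, got {W}")
    den = 1.0 - a_N * W
    if den <= 0.0:
        raise SingularMaintenanceError(
            f"maintenance denominator 1 - a_N*W = {den:.6g} <= 0 at W = {W:.6g} mg"
        )
    return a * W**beta - c * W / den


# ---------------------------------------------------------------------------
# Registry used by the fitting module
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateModel:
    """A named scalar growth-rate model ready for inverse-method fitting.

    ``rate(W, theta)`` evaluates dW/dt; ``default_bounds(ages, masses)``
    returns per-parameter (lo, hi) intervals; ``initial_guess`` returns a
    deterministic data-driven start; ``log_scale`` flags parameters whose
    multi-start samples are drawn log-uniformly (scale-type parameters).
    """

    name: str
    param_names: Tuple[str, ...]
    rate: Callable[[float, np.ndarray], float]
    default_bounds: Callable[[np.ndarray, np.ndarray], Sequence[Tuple[float, float]]]
    initial_guess: Callable[[np.ndarray, np.ndarray], np.ndarray]
    log_scale: Tuple[bool, ...]


def _early_allometric_coef(ages, masses, beta):
    """Rough supply coefficient from the first observed growth increment."""
    i = 1 if len(ages) > 1 else 0
    dt = max(ages[i] - ages[0], 1e-9)
    rate0 = max((masses[i] - masses[0]) / dt, 1e-9)
    Wmid = 0.5 * (masses[0] + masses[i])
    return rate0 / Wmid**beta


def _mgm_bounds(ages, masses):
    Wmax = float(np.max(masses))
    return [(1e-6, 1e3), (0.4, 1.2), (1e-6, 1e3), (0.0, 0.999 / Wmax)]


def _mgm_guess(ages, masses):
    Wmax = float(np.max(masses))
    beta0 = 0.75
    a0 = _early_allometric_coef(ages, masses, beta0)
    a_N0 = 0.45 / Wmax
    c0 = a0 * Wmax ** (beta0 - 1.0) * (1.0 - a_N0 * Wmax)
    return np.array([a0, beta0, max(c0, 1e-6), a_N0])


def _gsgm_bounds(ages, masses):
    return [(1e-6, 1e3), (0.01, 0.99), (1e-6, 1e3)]


def _gsgm_guess(ages, masses):
    Wmax = float(np.max(masses))
    b0 = 0.7
    a0 = _early_allometric_coef(ages, masses, b0)
    c0 = a0 * Wmax ** (b0 - 1.0)
    return np.array([a0, b0, max(c0, 1e-6)])


def _vb_bounds(ages, masses):
    return [(1e-6, 1e3), (1e-6, 1e3), (0.4, 0.99)]


def _vb_guess(ages, masses):
    Wmax = float(np.max(masses))
    beta0 = 2.0 / 3.0
    a0 = _early_allometric_coef(ages, masses, beta0)
    b0 = a0 * Wmax ** (beta0 - 1.0)
    return np.array([a0, max(b0, 1e-6), beta0])


def _logistic_bounds(ages, masses):
    Wmax = float(np.max(masses))
    return [(1e-6, 1e2), (Wmax * 0.5, Wmax * 10.0)]


def _logistic_guess(ages, masses):
    Wmax = float(np.max(masses))
    i = 1 if len(ages) > 1 else 0
    dt = max(ages[i] - ages[0], 1e-9)
    r0 = max((masses[i] - masses[0]) / dt / masses[0], 1e-6)
    return np.array([r0, Wmax * 1.05])


MODEL_REGISTRY: Dict[str, RateModel] = {}


def register_model(model: RateModel) -> None:
    """Register a rate model under its name (overwrites silently)."""
    MODEL_REGISTRY[model.name] = model


def get_model(name: str) -> RateModel:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise DomainError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


register_model(
    RateModel(
        name="MGM",
        param_names=("a", "beta", "c", "a_N"),
        rate=lambda W, th: mgm_reduced_rate(W, th[0], th[1], th[2], th[3]),
        default_bounds=_mgm_bounds,
        initial_guess=_mgm_guess,
        log_scale=(True, False, True, False),
    )
)
register_model(
    RateModel(
        name="GSGM",
        param_names=("a", "b", "c"),
        rate=lambda W, th: th[0] * W ** th[1] - th[2] * W,
        default_bounds=_gsgm_bounds,
        initial_guess=_gsgm_guess,
        log_scale=(True, False, True),
    )
)
register_model(
    RateModel(
        name="VB",
        param_names=("a", "b", "beta"),
        rate=lambda W, th: vb_rate(W, th[0], th[1], th[2]),
        default_bounds=_vb_bounds,
        initial_guess=_vb_guess,
        log_scale=(True, True, False),
    )
)
register_model(
    RateModel(
        name="logistic",
        param_names=("r", "K"),
        rate=lambda W, th: logistic_rate(W, th[0], th[1]),
        default_bounds=_logistic_bounds,
        initial_guess=_logistic_guess,
        log_scale=(True, False),
    )
)
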