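"""Inverse-method parameter estimation for registry growth models.

Fitting minimizes the sum of squared deviations between the integrated
model mass-at-age curve and averaged observations ("inverse method"),
from a seeded Latin-hypercube multi-start plus one deterministic
data-driven start.  The initial mass is fixed at the first observed mass
rather than estimated, matching the treatment of hatchling mass as known.

Goodness of fit uses the root-sum-of-squares ratio

    GF = 1 - sqrt(sum (O_i - E_i)^2) / sqrt(sum (O_i - Obar)^2)

which is 1 for a perfect fit and 0 for a constant-at-the-mean
prediction.  Note this is *not* the coefficient of determination R^2:
the ratio of root sums is taken, not of the sums themselves.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .comparators import RateModel, get_model
from .exceptions import DomainError, FitFailureError, MGMError

__all__ = ["FitResult", "goodness_of_fit", "sse_objective", "fit_model", "predict_masses"]

logger = logging.getLogger(__name__)

_PENALTY = 1e6  # per-point residual when integration fails


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-sum-of-squares goodness of fit; 1 = perfect, 0 = mean-level.

    Raises :class:`DomainError` for sequences shorter than 2, mismatched
    lengths, or an all-equal observed series (undefined denominator).
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(predicted, dtype=float)
    if O.shape != E.shape:
        raise DomainError(f"length mismatch: {O.shape} vs {E.shape}")
    if O.size < 2:
        raise DomainError("need at least 2 observations")
    denom = np.sqrt(np.sum((O - O.mean()) ** 2))
    if denom == 0.0:
        raise DomainError("observed values are all equal; GF denominator is zero")
    return 1.0 - float(np.sqrt(np.sum((O - E) ** 2)) / denom)


def _coerce_data(data) -> Tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with age/mass columns or a pair of sequences."""
    if isinstance(data, pd.DataFrame):
        ages = data["age"].to_numpy(dtype=float)
        masses = data["mass"].to_numpy(dtype=float)
    else:
        ages, masses = data
        ages = np.asarray(ages, dtype=float)
        masses = np.asarray(masses, dtype=float)
    if len(ages) != len(masses):
        raise DomainError("ages and masses differ in length")
    if np.any(np.diff(ages) <= 0):
        raise DomainError("data ages must be strictly increasing")
    if np.any(masses <= 0):
        raise DomainError("masses must be positive")
    return ages, masses


def predict_masses(
    model: RateModel,
    theta: np.ndarray,
    ages: np.ndarray,
    W0: float,
    rtol: float = 1e-9,
) -> Optional[np.ndarray]:
    """Integrate the model from (ages[0], W0) and sample at the data ages.

    Returns None when the trajectory cannot be produced (solver failure,
    a singular rate encountered anywhere along the trajectory, or
    non-finite masses) so callers can apply a penalty.
    """
    singular = False

    def safe_rate(t, y):
        nonlocal singular
        W = y[0]
        if W <= 0.0 or not np.isfinite(W):
            singular = True
            return [0.0]
        try:
            return [model.rate(W, theta)]
        except MGMError:
            singular = True
            return [-1e9]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = solve_ivp(
                safe_rate,
                (ages[0], ages[-1]),
                [W0],
                method="LSODA",
                t_eval=ages,
                rtol=rtol,
                atol=1e-12,
            )
    except (MGMError, ValueError, OverflowError):
        return None
    if singular or not res.success or res.y.shape[1] != len(ages):
        return None
    pred = res.y[0]
    if not np.all(np.isfinite(pred)):
        return None
    return pred


def sse_objective(
    param_vector: Sequence[float],
    data,
    model: str = "MGM",
    W0: Optional[float] = None,
    rtol: float = 1e-9,
) -> float:
    """Sum of squared deviations between model curve and averaged data (mg^2).

    Integration failures return a large penalty (and log a warning) so
    derivative-free or bounded optimizers can continue past bad regions.
    """
    ages, masses = _coerce_data(data)
    rate_model = get_model(model)
    theta = np.asarray(param_vector, dtype=float)
    pred = predict_masses(rate_model, theta, ages, masses[0] if W0 is None else W0, rtol)
    if pred is None:
        logger.warning("integration failed for %s at theta=%s; penalty applied", model, theta)
        return float(_PENALTY**2 * len(ages))
    return float(np.sum((masses - pred) ** 2))


@dataclass
class FitResult:
    """Outcome of a multi-start inverse-method fit."""

    model_name: str
    params: Dict[str, float]
    sse: float
    gf: float
    n_obs: int
    n_starts: int
    converged: List[bool]
    start_sses: List[float]
    seed: int
    W0: float
    predicted: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": self.params,
            "sse": self.sse,
            "gf": self.gf,
            "n_obs": self.n_obs,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "start_sses": self.start_sses,
            "seed": self.seed,
            "W0": self.W0,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _sample_starts(
    bounds: Sequence[Tuple[float, float]],
    log_scale: Sequence[bool],
    n: int,
    seed: int,
) -> np.ndarray:
    """Seeded Latin-hypercube start points; scale parameters sampled
    log-uniformly within their bounds."""
    k = len(bounds)
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    u = sampler.random(n)
    starts = np.empty_like(u)
    for j, ((lo, hi), is_log) in enumerate(zip(bounds, log_scale)):
        if is_log:
            lo_ = max(lo, 1e-9)
            starts[:, j] = np.exp(
                np.log(lo_) + u[:, j] * (np.log(hi) - np.log(lo_))
            )
        else:
            starts[:, j] = lo + u[:, j] * (hi - lo)
    return starts


def fit_model(
    data,
    model: str = "MGM",
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    n_starts: int = 16,
    seed: int = 0,
    W0: Optional[float] = None,
    rtol: float = 1e-9,
) -> FitResult:
    """Fit a registered growth model to averaged (age, mass) data.

    Runs bounded trust-region least squares from ``n_starts`` start
    points (one deterministic data-driven guess plus a seeded
    Latin-hypercube sample) and returns the best result with per-start
    diagnostics.  Identical inputs and seed reproduce the result exactly.
    """
    ages, masses = _coerce_data(data)
    rate_model = get_model(model)
    if W0 is None:
        W0 = float(masses[0])
    bounds = list(bounds) if bounds is not None else list(rate_model.default_bounds(ages, masses))
    if len(bounds) != len(rate_model.param_names):
        raise DomainError(
            f"{model} takes {len(rate_model.param_names)} parameters, got {len(bounds)} bounds"
        )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise DomainError("bounds must be finite")

    def residuals(theta: np.ndarray) -> np.ndarray:
        pred = predict_masses(rate_model, theta, ages, W0, rtol)
        if pred is None:
            return np.full(len(ages), _PENALTY)
        return pred - masses

    guess = np.clip(rate_model.initial_guess(ages, masses), lo, hi)
    n_random = max(n_starts - 1, 0)
    starts = [guess]
    if n_random:
        starts.extend(_sample_starts(bounds, rate_model.log_scale, n_random, seed))

    best = None
    converged: List[bool] = []
    start_sses: List[float] = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-10,
                max_nfev=400,
            )
            ok = bool(res.success)
            sse = float(np.sum(res.fun**2))
        except (MGMError, ValueError) as exc:
            logger.warning("start %s failed: %s", x0, exc)
            ok, sse, res = False, float("inf"), None
        converged.append(ok)
        start_sses.append(sse)
        if res is not None and (best is None or sse < best[1]):
            best = (res.x.copy(), sse)

    if best is None or not any(converged):
        raise FitFailureError(
            f"no start converged for model {model}; per-start SSE: {start_sses}"
        )
    theta_best, sse_best = best
    pred = predict_masses(rate_model, theta_best, ages, W0, rtol)
    if pred is None:
        raise FitFailureError(f"best start of model {model} does not integrate")
    gf = goodness_of_fit(masses, pred)
    return FitResult(
        model_name=model,
        params={n: float(v) for n, v in zip(rate_model.param_names, theta_best)},
        sse=float(np.sum((pred - masses) ** 2)),
        gf=gf,
        n_obs=len(ages),
        n_starts=len(starts),
        converged=converged,
        start_sses=start_sses,
        seed=seed,
        W0=W0,
        predicted=pred,
    )
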