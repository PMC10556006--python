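"""Growth ODE assembly, integration and trajectory summaries.

The growth rate is the energy balance solved for dW/dt:

    dW/dt = [e*S(phi, W) - R_F(S) - R_M(phi, W)] / [E_M(W) + E_S(W)]

Under the simplest relevant assumptions (constant composition, lumped
tissues, proportional feeding cost) this becomes

    dW/dt = (e - k_F) * phi * alpha * W**beta / (E_M + E_S)
            - gamma_B * W / [(E_M + E_S) * (1 - a_N * W**b_N * phi**delta)]

which with b_N = 0 and fixed phi is a von Bertalanffy equation
dW/dt = a*W**beta - b*W, and with b_N = 1, phi = 1 the four-parameter
ad-libitum form dW/dt = a*W**beta - c*W/(1 - a_N*W).

Integration uses an adaptive stiff-capable solver (LSODA) with tight
default tolerances (rtol 1e-9, atol 1e-12 mg) and dense output, so ages
at mass fractions can be read off by root-finding on the interpolant.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .components import (
    CompositionParams,
    EnergyBudget,
    FeedingParams,
    IngestionParams,
    MaintenanceParams,
    energy_density_EM,
    feeding_cost,
    growth_overhead_ES,
    ingestion_rate,
    maintenance_cost,
)
from .exceptions import (
    DomainError,
    IncompleteTrajectoryError,
    IntegrationError,
    MGMError,
    NoUltimateMassError,
    SingularMaintenanceError,
)

__all__ = [
    "ModelParams",
    "Trajectory",
    "TrajectorySummary",
    "PiecewisePhi",
    "growth_rate",
    "integrate_growth",
    "integrate_rate",
    "ultimate_mass",
    "summarize_trajectory",
    "food_restriction_sweep",
    "energy_budget_series",
]

_VARIANTS = ("full", "simplified")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the maintenance-growth model.

    ``variant`` selects the maintenance path: ``"full"`` evaluates the
    two-tissue maintenance with the reproductive mass share p_R(W);
    ``"simplified"`` treats all mass as somatic (p_R = 0), which is the
    lumped single-tissue form.  Both use the same ingestion, composition
    and feeding components.
    """

    ingestion: IngestionParams
    composition: CompositionParams = field(default_factory=CompositionParams)
    feeding: FeedingParams = field(default_factory=FeedingParams)
    maintenance: MaintenanceParams = field(default_factory=MaintenanceParams)
    e: float = 0.8
    variant: str = "simplified"

    def __post_init__(self) -> None:
        if not 0.0 < self.e < 1.0:
            raise DomainError(f"assimilation efficiency e must lie in (0, 1), got {self.e}")
        if self.variant not in _VARIANTS:
            raise DomainError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.feeding.custom_fn is None and self.e - self.feeding.k_F <= 0:
            raise DomainError(
                f"e - k_F = {self.e - self.feeding.k_F:.4g} <= 0: assimilation "
                "cannot cover proportional feeding costs, growth is impossible"
            )

    def with_delta(self, delta: float) -> "ModelParams":
        """Copy with the defence reduction exponent replaced."""
        m = dataclasses.replace(self.maintenance, delta=delta)
        return dataclasses.replace(self, maintenance=m)


class PiecewisePhi:
    """Piecewise-constant food-acquirement schedule phi(t).

    ``breaks`` are ascending ages (days) at which the level changes;
    ``values`` has one more entry than ``breaks``.
    """

    def __init__(self, breaks: Sequence[float], values: Sequence[float]):
        breaks = np.asarray(breaks, dtype=float)
        values = np.asarray(values, dtype=float)
        if len(values) != len(breaks) + 1:
            raise DomainError("need len(values) == len(breaks) + 1")
        if len(breaks) and np.any(np.diff(breaks) <= 0):
            raise DomainError("breaks must be strictly increasing")
        if np.any((values < 0) | (values > 1)):
            raise DomainError("phi values must lie in [0, 1]")
        self.breaks = breaks
        self.values = values

    def __call__(self, t: float) -> float:
        return float(self.values[np.searchsorted(self.breaks, t, side="right")])


PhiLike = Union[float, PiecewisePhi]


def growth_rate(W: float, phi: float, p: ModelParams) -> float:
    """Instantaneous growth rate dW/dt (mg/day) at mass ``W`` and level ``phi``.

    Negative values are returned as-is (the state is then outside the
    default no-shrinkage integration domain); a diverging maintenance
    denominator raises :class:`SingularMaintenanceError`.
    """
    S = ingestion_rate(phi, W, p.ingestion)
    E_M = energy_density_EM(W, p.composition)
    E_S = growth_overhead_ES(W, p.composition)
    R_F = feeding_cost(S, p.feeding)
    if p.variant == "full":
        p_R = p.composition.fractions_at(W)["p_R"]
    else:
        p_R = 0.0
    R_M = maintenance_cost(phi, W, p.maintenance, p_R)
    return (p.e * S - R_F - R_M) / (E_M + E_S)


def _singular_mass(p: ModelParams, phi: float) -> float:
    """Smallest body mass where a maintenance denominator vanishes (inf if none).

    Exact for the simplified variant and for constant p_R; callers only use
    it as an upper search bound, so infinity is a safe fallback.
    """
    if phi == 0.0:
        if p.maintenance.delta > 0:
            return math.inf
        phi_term = 1.0
    else:
        phi_term = phi**p.maintenance.delta
    candidates = []
    if p.variant == "full":
        p_R = p.composition.p_R
        if callable(p_R):
            return math.inf
        shares = ((1.0 - p_R, p.maintenance.a_NS, p.maintenance.b_NS),
                  (p_R, p.maintenance.a_NR, p.maintenance.b_NR))
    else:
        shares = ((1.0, p.maintenance.a_NS, p.maintenance.b_NS),)
    for share, a_N, b_N in shares:
        if share > 0 and a_N > 0 and b_N > 0:
            W_t = (1.0 / (a_N * phi_term)) ** (1.0 / b_N)
            candidates.append(W_t / share)
    return min(candidates) if candidates else math.inf


def ultimate_mass(p: ModelParams, phi: float, W_lo: float = 1e-3) -> float:
    """Ultimate (asymptotic) body mass W_U: positive root of dW/dt = 0.

    Brackets the root between ``W_lo`` (where growth must be positive) and
    either the maintenance singularity or a geometrically expanded upper
    bound, then applies a bracketing root-finder at relative tolerance
    ~1e-12.  Raises :class:`NoUltimateMassError` if growth is already
    non-positive at ``W_lo`` (immediate decline) or never turns negative
    (indefinite growth).
    """
    f = lambda W: growth_rate(W, phi, p)
    if f(W_lo) <= 0:
        raise NoUltimateMassError(
            f"growth rate is non-positive already at W = {W_lo} mg; "
            "no growth phase exists under these parameters"
        )
    W_sing = _singular_mass(p, phi)
    if math.isfinite(W_sing):
        W_hi = W_sing * (1.0 - 1e-12)
        if f(W_hi) >= 0:  # pragma: no cover - defensive
            raise NoUltimateMassError("no sign change below the maintenance singularity")
    else:
        W_hi = max(2.0 * W_lo, 1.0)
        for _ in range(80):
            try:
                if f(W_hi) < 0:
                    break
            except SingularMaintenanceError:
                # Overshot a singularity the analytic probe missed: bisect back
                # to a valid negative-growth point.
                lo, hi = W_hi / 2.0, W_hi
                for _ in range(200):
                    mid = 0.5 * (lo + hi)
                    try:
                        if f(mid) < 0:
                            W_hi = mid
                            break
                        lo = mid
                    except SingularMaintenanceError:
                        hi = mid
                else:  # pragma: no cover
                    raise NoUltimateMassError("could not bracket the growth fixed point")
                break
            W_hi *= 2.0
        else:
            raise NoUltimateMassError(
                f"growth rate stays positive up to W = {W_hi:.3g} mg; "
                "indefinite growth under the given parameters"
            )
    return float(brentq(f, W_lo, W_hi, xtol=1e-14, rtol=1e-13, maxiter=200))


@dataclass
class Trajectory:
    """Time-ordered solution of the growth equation.

    ``ages`` (days, strictly increasing) and ``masses`` (mg) are the
    sampled states; ``sol`` is the solver's dense interpolant, used for
    inverse lookups.  ``phi`` records the schedule the run used.
    """

    ages: np.ndarray
    masses: np.ndarray
    phi: PhiLike
    params: ModelParams
    sol: Optional[Callable[[float], float]] = None
    terminated_early: bool = False
    termination_reason: str = ""

    @property
    def W0(self) -> float:
        return float(self.masses[0])

    @property
    def t_end(self) -> float:
        return float(self.ages[-1])

    def mass_at(self, t: float) -> float:
        if self.sol is not None:
            return float(self.sol(t))
        return float(np.interp(t, self.ages, self.masses))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "mass": self.masses})


def integrate_rate(
    rate: Callable[[float], float],
    W0: float,
    t_span: tuple,
    ages: Optional[np.ndarray] = None,
    stop_at_mass: Optional[float] = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    max_mass: Optional[float] = None,
) -> "solve_ivp":
    """Integrate a scalar mass-growth rate function; shared solver front-end.

    ``stop_at_mass`` installs a terminal upward-crossing event;
    ``max_mass`` installs a terminal guard (used to stop short of a
    maintenance singularity).  Returns the raw solver result.
    """
    events = []
    if stop_at_mass is not None:
        ev = lambda t, y: y[0] - stop_at_mass
        ev.terminal = True
        ev.direction = 1
        events.append(ev)
    if max_mass is not None and math.isfinite(max_mass):
        guard = lambda t, y: y[0] - max_mass
        guard.terminal = True
        guard.direction = 1
        events.append(guard)
    res = solve_ivp(
        lambda t, y: [rate(y[0])],
        t_span,
        [W0],
        method="LSODA",
        t_eval=ages,
        dense_output=True,
        rtol=rtol,
        atol=atol,
        events=events or None,
    )
    return res


def integrate_growth(
    W0: float,
    t_end: float,
    p: ModelParams,
    phi: PhiLike = 1.0,
    ages: Optional[Sequence[float]] = None,
    stop_at_mass: Optional[float] = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    allow_shrinkage: bool = False,
) -> Trajectory:
    """Integrate the growth equation from ``W0`` over ``[0, t_end]`` days.

    ``phi`` may be a constant in [0, 1] or a :class:`PiecewisePhi`
    schedule (integrated segment by segment so the solver never steps
    across a discontinuity).  By default a negative initial growth rate is
    rejected; shrinking trajectories require ``allow_shrinkage=True``.
    """
    if W0 <= 0:
        raise DomainError(f"W0 must be > 0, got {W0}")
    if t_end <= 0:
        raise DomainError(f"t_end must be > 0, got {t_end}")
    ages_arr = None if ages is None else np.asarray(ages, dtype=float)

    if isinstance(phi, PiecewisePhi):
        return _integrate_schedule(
            W0, t_end, p, phi, ages_arr, rtol, atol, allow_shrinkage
        )

    phi_val = float(phi)
    r0 = growth_rate(W0, phi_val, p)
    if not math.isfinite(r0):
        raise IntegrationError(f"non-finite growth rate at W0 = {W0}")
    if r0 < 0 and not allow_shrinkage:
        raise NoUltimateMassError(
            f"growth rate at W0 = {W0} mg is negative ({r0:.4g} mg/day); "
            "pass allow_shrinkage=True to integrate a declining trajectory"
        )
    W_sing = _singular_mass(p, phi_val)
    guard = W_sing * (1.0 - 1e-9) if math.isfinite(W_sing) else None
    res = integrate_rate(
        lambda W: growth_rate(W, phi_val, p),
        W0,
        (0.0, t_end),
        ages=ages_arr,
        stop_at_mass=stop_at_mass,
        rtol=rtol,
        atol=atol,
        max_mass=guard,
    )
    if not res.success and res.status != 1:
        raise IntegrationError(f"ODE solver failed: {res.message}")
    terminated = res.status == 1
    reason = ""
    if terminated:
        # events were registered stop-event first, singularity guard last
        stop_hit = stop_at_mass is not None and len(res.t_events[0]) > 0
        guard_hit = guard is not None and len(res.t_events[-1]) > 0
        if stop_hit:
            reason = f"reached stop mass {stop_at_mass:.6g} mg"
        elif guard_hit:
            reason = f"approached maintenance singularity near W = {W_sing:.6g} mg"
        else:  # pragma: no cover
            reason = "terminal event"
    return Trajectory(
        ages=np.asarray(res.t, dtype=float),
        masses=np.asarray(res.y[0], dtype=float),
        phi=phi_val,
        params=p,
        sol=lambda s, _sol=res.sol: float(_sol(s)[0]),
        terminated_early=terminated,
        termination_reason=reason,
    )


def _integrate_schedule(W0, t_end, p, schedule, ages, rtol, atol, allow_shrinkage):
    """Segment-wise integration over a piecewise-constant phi schedule."""
    edges = [0.0] + [b for b in schedule.breaks if 0.0 < b < t_end] + [t_end]
    t_all, y_all = [], []
    segments = []
    W = W0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        phi_val = schedule(0.5 * (t0 + t1))
        r0 = growth_rate(W, phi_val, p)
        if r0 < 0 and not allow_shrinkage:
            raise NoUltimateMassError(
                f"negative growth rate at segment start t = {t0} (phi = {phi_val})"
            )
        W_sing = _singular_mass(p, phi_val)
        guard = W_sing * (1.0 - 1e-9) if math.isfinite(W_sing) else None
        seg_ages = None
        if ages is not None:
            mask = (ages >= t0) & (ages <= t1)
            seg_ages = ages[mask]
            if len(seg_ages) == 0:
                seg_ages = None
        res = integrate_rate(
            lambda m, _phi=phi_val: growth_rate(m, _phi, p),
            W, (t0, t1), ages=seg_ages, rtol=rtol, atol=atol, max_mass=guard,
        )
        if not res.success and res.status != 1:
            raise IntegrationError(f"ODE solver failed on [{t0}, {t1}]: {res.message}")
        segments.append((t0, t1, res.sol))
        t_all.append(res.t)
        y_all.append(res.y[0])
        W = float(res.y[0][-1])

    t_cat = np.concatenate(t_all)
    y_cat = np.concatenate(y_all)
    keep = np.concatenate([[True], np.diff(t_cat) > 0])
    t_cat, y_cat = t_cat[keep], y_cat[keep]

    def dense(s: float) -> float:
        for t0, t1, sol in segments:
            if t0 <= s <= t1:
                return float(sol(s)[0])
        raise DomainError(f"age {s} outside integrated range")

    return Trajectory(
        ages=t_cat, masses=y_cat, phi=schedule, params=p, sol=dense
    )


@dataclass
class TrajectorySummary:
    """Derived growth descriptors of one trajectory.

    - ``W_U``: ultimate mass (mg), from the rate fixed point (not the
      trajectory endpoint);
    - ``Wdot_max``/``W_star``: maximum growth rate (mg/day) and the mass at
      which it occurs, from continuous maximization of the rate function;
    - ``W95``/``t95``: 0.95*W_U and the first age reaching it;
    - ``omega_star`` = W_star / W_U, the dimensionless hump position;
    - ``Omega`` = Wdot_max / [(W95 - W0) / t95], maximum over average
      life-time growth rate, with "life time" operationalized as t95.
    """

    W_U: float
    Wdot_max: float
    W_star: float
    W95: float
    t95: float
    omega_star: float
    Omega: float
    W0: float
    phi: float
    _age_lookup: Callable[[float], float] = field(repr=False, default=None)

    def t_at_fraction(self, omega: float) -> float:
        """First age (days) at which mass reaches ``omega * W_U``."""
        return self._age_lookup(omega)


def _first_age_at_mass(traj: Trajectory, target: float) -> float:
    """Invert the dense solution for the first crossing of ``target`` mass."""
    if target <= traj.masses[0]:
        return float(traj.ages[0])
    if target > traj.masses.max():
        raise IncompleteTrajectoryError(
            f"trajectory peaks at {traj.masses.max():.6g} mg, below target "
            f"{target:.6g} mg; integrate to a larger t_end"
        )
    idx = int(np.searchsorted(traj.masses, target))
    t_lo = traj.ages[max(idx - 1, 0)]
    t_hi = traj.ages[min(idx, len(traj.ages) - 1)]
    if traj.sol is None or t_hi <= t_lo:
        return float(np.interp(target, traj.masses, traj.ages))
    return float(brentq(lambda t: traj.sol(t) - target, t_lo, t_hi, xtol=1e-12))


def summarize_trajectory(traj: Trajectory, p: Optional[ModelParams] = None) -> TrajectorySummary:
    """Summarize a constant-phi trajectory into its growth descriptors.

    Requires the trajectory to reach at least 0.95 * W_U, otherwise an
    :class:`IncompleteTrajectoryError` suggests a longer integration.
    W_star and Wdot_max come from bounded scalar maximization of the
    analytic rate function over (0, W_U), avoiding sampling-grid
    artifacts.
    """
    p = p or traj.params
    if isinstance(traj.phi, PiecewisePhi):
        raise DomainError("summaries are defined for constant-phi trajectories")
    phi = float(traj.phi)
    W0 = traj.W0
    W_U = ultimate_mass(p, phi, W_lo=min(W0, 1e-3))
    res = minimize_scalar(
        lambda W: -growth_rate(W, phi, p),
        bounds=(W_U * 1e-9, W_U * (1.0 - 1e-12)),
        method="bounded",
        options={"xatol": W_U * 1e-11},
    )
    W_star = float(res.x)
    Wdot_max = float(-res.fun)
    W95 = 0.95 * W_U
    t95 = _first_age_at_mass(traj, W95)
    avg_rate = (W95 - W0) / t95 if t95 > 0 else math.nan
    Omega = Wdot_max / avg_rate if avg_rate and avg_rate > 0 else math.nan

    def age_lookup(omega: float, _traj=traj, _WU=W_U) -> float:
        if not 0.0 < omega <= 1.0:
            raise DomainError(f"mass fraction must lie in (0, 1], got {omega}")
        return _first_age_at_mass(_traj, omega * _WU)

    return TrajectorySummary(
        W_U=W_U,
        Wdot_max=Wdot_max,
        W_star=W_star,
        W95=W95,
        t95=t95,
        omega_star=W_star / W_U,
        Omega=Omega,
        W0=W0,
        phi=phi,
        _age_lookup=age_lookup,
    )


def summarize_rate(
    rate: Callable[[float], float],
    W0: float,
    t_cap: float = 1e6,
) -> TrajectorySummary:
    """Summarize growth implied by an arbitrary scalar rate function.

    Same descriptors as :func:`summarize_trajectory` but for a raw
    dW/dt(W) callable (e.g. a fitted comparator model): W_U by bracketed
    root-finding above ``W0``, the hump by bounded maximization, t95 by
    integrating to the 95% crossing.
    """
    if rate(W0) <= 0:
        raise NoUltimateMassError(f"rate is non-positive at W0 = {W0}")
    W_hi = max(2.0 * W0, 1.0)
    for _ in range(200):
        if rate(W_hi) < 0:
            break
        W_hi *= 2.0
    else:
        raise NoUltimateMassError("rate never turns negative; no ultimate mass")
    W_U = float(brentq(rate, W0, W_hi, xtol=1e-14, rtol=1e-13))
    res = minimize_scalar(
        lambda W: -rate(W),
        bounds=(W_U * 1e-9, W_U * (1.0 - 1e-12)),
        method="bounded",
        options={"xatol": W_U * 1e-11},
    )
    W_star, Wdot_max = float(res.x), float(-res.fun)
    W95 = 0.95 * W_U
    ivp = integrate_rate(rate, W0, (0.0, t_cap), stop_at_mass=W95)
    if ivp.status != 1 or len(ivp.t_events[0]) == 0:
        raise IncompleteTrajectoryError("0.95*W_U not reached within the time cap")
    t95 = float(ivp.t_events[0][0])
    traj = Trajectory(
        ages=ivp.t, masses=ivp.y[0], phi=math.nan, params=None,
        sol=lambda s, _sol=ivp.sol: float(_sol(s)[0]),
    )
    avg = (W95 - W0) / t95

    def age_lookup(omega: float, _traj=traj, _WU=W_U) -> float:
        if not 0.0 < omega <= 1.0:
            raise DomainError(f"mass fraction must lie in (0, 1], got {omega}")
        return _first_age_at_mass(_traj, omega * _WU)

    return TrajectorySummary(
        W_U=W_U, Wdot_max=Wdot_max, W_star=W_star, W95=W95, t95=t95,
        omega_star=W_star / W_U, Omega=Wdot_max / avg, W0=W0, phi=math.nan,
        _age_lookup=age_lookup,
    )


def food_restriction_sweep(
    p: ModelParams,
    phi_grid: Sequence[float],
    delta_grid: Sequence[float],
    W0: float = 0.67,
    fractions: Sequence[float] = (0.5, 0.75, 0.95),
    t_cap: float = 1e6,
) -> pd.DataFrame:
    """Summarize one trajectory per (phi, delta) grid cell.

    Each cell integrates to the first age reaching 0.95 * W_U (capped at
    ``t_cap`` days) and records W_U, W95, t95 and the ages at the
    requested mass fractions.  Cell failures (e.g. no growth at very low
    phi) are recorded in the ``status``/``message`` columns instead of
    aborting the sweep.  Rows are sorted by (delta, phi).
    """
    fractions = sorted(set(fractions) | {0.95})
    rows = []
    for delta in delta_grid:
        p_d = p.with_delta(float(delta))
        for phi in phi_grid:
            row: Dict[str, object] = {"phi": float(phi), "delta": float(delta)}
            try:
                W_U = ultimate_mass(p_d, float(phi), W_lo=min(W0, 1e-3))
                traj = integrate_growth(
                    W0, t_cap, p_d, float(phi), stop_at_mass=0.95 * W_U
                )
                summ = summarize_trajectory(traj, p_d)
                row.update(
                    W_U=summ.W_U,
                    W95=summ.W95,
                    t95=summ.t95,
                    Wdot_max=summ.Wdot_max,
                    W_star=summ.W_star,
                    omega_star=summ.omega_star,
                )
                for om in fractions:
                    row[f"t_at_{om:g}"] = summ.t_at_fraction(om)
                row["status"] = "ok"
                row["message"] = ""
            except MGMError as exc:
                row["status"] = "failed"
                row["message"] = str(exc)
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["delta", "phi"]).reset_index(drop=True)
    return df


def energy_budget_series(traj: Trajectory, p: Optional[ModelParams] = None):
    """Recompute the full energy budget at every sampled age of a trajectory.

    Returns ``(budgets, max_rel_residual)`` where the residual of the
    balance e*S - R_M - R_F - R_G - G is reported relative to the
    assimilation rate e*S at that age (ages with S = 0 use the absolute
    residual).
    """
    p = p or traj.params
    budgets = []
    max_rel = 0.0
    for t, W in zip(traj.ages, traj.masses):
        phi = traj.phi(t) if isinstance(traj.phi, PiecewisePhi) else float(traj.phi)
        S = ingestion_rate(phi, W, p.ingestion)
        E_M = energy_density_EM(W, p.composition)
        E_S = growth_overhead_ES(W, p.composition)
        R_F = feeding_cost(S, p.feeding)
        p_R = p.composition.fractions_at(W)["p_R"] if p.variant == "full" else 0.0
        R_M = maintenance_cost(phi, W, p.maintenance, p_R)
        dWdt = (p.e * S - R_F - R_M) / (E_M + E_S)
        R_G = E_S * dWdt
        G = E_M * dWdt
        assim = p.e * S
        residual = assim - R_M - R_F - R_G - G
        rel = abs(residual) / assim if assim > 0 else abs(residual)
        max_rel = max(max_rel, rel)
        budgets.append(
            EnergyBudget(
                age=float(t), W=float(W), S=S, assimilated=assim,
                R_M=R_M, R_F=R_F, R_G=R_G, G=G, residual=residual,
            )
        )
    return budgets, max_rel
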