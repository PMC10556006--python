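"""Reduction pipeline for individual mass-at-age cohort tables.

The pipeline mirrors the treatment of self-thinning cricket cohorts:

1. pool all individuals of a starting density and average body mass per
   age (:func:`average_cohort`);
2. derive growth rates from difference ratios of the averaged series,
   linearly interpolated back to the observation ages
   (:func:`rates_from_differences`);
3. fit a quadratic to (non-averaged) growth-rate-vs-mass points to
   obtain a smooth rate curve and read off the maximum growth rate and
   the mass where it occurs (:func:`smooth_rate_curve`);
4. integrate the quadratic rate curve into a smooth mass-at-age curve
   and extract the ultimate mass, t95 and ages at mass fractions
   (:func:`smooth_growth_curve`);
5. map starting densities to a normalised food availability in (0, 1]
   (:func:`normalized_food_availability`) and summarize maturation per
   density and sex (:func:`maturation_summary`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import DomainError, IncompleteTrajectoryError, IntegrationError

__all__ = [
    "COHORT_COLUMNS",
    "CohortTable",
    "AveragedGrowthData",
    "RateCurveFit",
    "SmoothGrowthCurve",
    "average_cohort",
    "rates_from_differences",
    "smooth_rate_curve",
    "smooth_growth_curve",
    "normalized_food_availability",
    "maturation_summary",
]

#: Canonical column set of a cohort table (CSV header row, '.' decimal).
COHORT_COLUMNS = [
    "cohort_id",
    "starting_density",
    "individual_id",
    "age",
    "mass",
    "sex",
    "maturation_age",
    "maturation_mass",
]

_REQUIRED = COHORT_COLUMNS[:5]


@dataclass
class CohortTable:
    """Individual-level mass-at-age records, one row per measurement.

    ``sex`` and the maturation columns are optional (NaN/empty when not
    recorded).  ``maturation_age``/``maturation_mass`` are repeated on
    every row of an individual that matured.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise DomainError(f"cohort table is missing columns {missing}")
        for col in ("sex", "maturation_age", "maturation_mass"):
            if col not in self.df.columns:
                self.df[col] = np.nan
        if (self.df["mass"] <= 0).any():
            raise DomainError("all masses must be > 0")
        if (self.df["age"] < 0).any():
            raise DomainError("ages must be >= 0")

    @property
    def densities(self) -> np.ndarray:
        return np.sort(self.df["starting_density"].unique())

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False, columns=COHORT_COLUMNS)


@dataclass
class AveragedGrowthData:
    """Per-density averaged growth series.

    ``df`` has one row per (starting_density, age) with columns
    ``mean_mass``, ``n_individuals`` and, after
    :func:`rates_from_differences`, ``rate``.
    """

    df: pd.DataFrame

    def for_density(self, density) -> Tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["starting_density"] == density].sort_values("age")
        if sub.empty:
            raise DomainError(f"no averaged data for density {density}")
        return sub["age"].to_numpy(), sub["mean_mass"].to_numpy()

    def rates_for_density(self, density) -> Tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["starting_density"] == density].sort_values("age")
        if "rate" not in sub.columns or sub["rate"].isna().all():
            raise DomainError("rates not computed; run rates_from_differences first")
        return sub["mean_mass"].to_numpy(), sub["rate"].to_numpy()


def average_cohort(table: CohortTable) -> AveragedGrowthData:
    """Average body mass per (starting density, age), pooled across all
    individuals of all replicate cohorts of that density (never a
    mean of cohort means).  Densities with fewer than two distinct ages
    are skipped with a warning.
    """
    grouped = (
        table.df.groupby(["starting_density", "age"])["mass"]
        .agg(mean_mass="mean", n_individuals="size")
        .reset_index()
    )
    keep = []
    for d, sub in grouped.groupby("starting_density"):
        if sub["age"].nunique() < 2:
            warnings.warn(f"density {d}: fewer than 2 ages, skipped", stacklevel=2)
            continue
        keep.append(sub)
    if not keep:
        raise DomainError("no density group has at least 2 ages")
    return AveragedGrowthData(pd.concat(keep, ignore_index=True))


def rates_from_differences(avg: AveragedGrowthData) -> AveragedGrowthData:
    """Growth rates at the observation ages via difference ratios.

    Forward differences of the averaged series give rates at interval
    midpoints; linear interpolation maps them back to the observation
    ages, with one-sided (nearest-midpoint) values at the endpoints.
    Returns a copy of the averaged data with a ``rate`` column.
    """
    out = []
    for d, sub in avg.df.groupby("starting_density"):
        sub = sub.sort_values("age").copy()
        t = sub["age"].to_numpy(dtype=float)
        W = sub["mean_mass"].to_numpy(dtype=float)
        if len(t) < 3:
            raise DomainError(f"density {d}: need >= 3 ages for difference ratios")
        if np.any(np.diff(t) == 0):
            raise DomainError(f"density {d}: duplicated ages")
        mid = 0.5 * (t[:-1] + t[1:])
        r = np.diff(W) / np.diff(t)
        sub["rate"] = np.interp(t, mid, r)
        out.append(sub)
    return AveragedGrowthData(pd.concat(out, ignore_index=True))


@dataclass
class RateCurveFit:
    """Least-squares quadratic of growth rate on body mass.

    ``coef`` is (c2, c1, c0), highest degree first.  ``W_star`` and
    ``Wdot_max`` are the vertex coordinates when the parabola is
    concave-down; ``has_maximum`` is False otherwise.
    """

    coef: np.ndarray
    W_star: Optional[float]
    Wdot_max: Optional[float]
    has_maximum: bool
    vertex_in_range: bool
    mass_range: Tuple[float, float]
    n_points: int

    def __call__(self, W):
        return np.polyval(self.coef, W)


def smooth_rate_curve(
    masses: Sequence[float],
    rates: Sequence[float],
    trim_late_departures: bool = False,
    trim_factor: float = 2.0,
) -> RateCurveFit:
    """Fit rate = q(W) = c2*W^2 + c1*W + c0 by least squares.

    ``trim_late_departures`` refits once after dropping points above the
    vertex whose absolute residual exceeds ``trim_factor`` times the RMS
    residual — a pragmatic guard for strongly restricted groups whose
    late-age points fall off a parabola.  Warns when the parabola is
    concave-up (no maximum) or the vertex lies outside the observed mass
    range.
    """
    W = np.asarray(masses, dtype=float)
    r = np.asarray(rates, dtype=float)
    if W.shape != r.shape:
        raise DomainError("masses and rates differ in length")
    if len(np.unique(W)) < 3:
        raise DomainError("need >= 3 distinct masses for a quadratic fit")
    coef = np.polyfit(W, r, 2)

    if trim_late_departures and coef[0] < 0:
        resid = r - np.polyval(coef, W)
        rms = float(np.sqrt(np.mean(resid**2)))
        vertex = -coef[1] / (2.0 * coef[0])
        keep = ~((W > vertex) & (np.abs(resid) > trim_factor * rms))
        if keep.sum() >= 3 and keep.sum() < len(W):
            coef = np.polyfit(W[keep], r[keep], 2)

    c2, c1, _ = coef
    if c2 >= 0:
        warnings.warn("rate-vs-mass quadratic is concave-up: no interior maximum", stacklevel=2)
        return RateCurveFit(coef, None, None, False, False, (W.min(), W.max()), len(W))
    W_star = -c1 / (2.0 * c2)
    Wdot_max = float(np.polyval(coef, W_star))
    in_range = bool(W.min() <= W_star <= W.max())
    if not in_range:
        warnings.warn(
            f"quadratic vertex W* = {W_star:.4g} lies outside the observed "
            f"mass range [{W.min():.4g}, {W.max():.4g}]",
            stacklevel=2,
        )
    return RateCurveFit(coef, float(W_star), Wdot_max, True, in_range, (W.min(), W.max()), len(W))


@dataclass
class SmoothGrowthCurve:
    """Mass-at-age curve obtained by integrating a quadratic rate curve."""

    ages: np.ndarray
    masses: np.ndarray
    W_U: float
    t95: float
    _sol: Callable[[float], float] = field(repr=False, default=None)

    def t_at_fraction(self, omega: float) -> float:
        """First age at which mass reaches ``omega * W_U``."""
        if not 0.0 < omega < 1.0:
            raise DomainError(f"fraction must lie in (0, 1), got {omega}")
        target = omega * self.W_U
        if target <= self.masses[0]:
            return float(self.ages[0])
        if target > self.masses[-1]:
            raise IncompleteTrajectoryError(
                f"smooth curve ends at {self.masses[-1]:.6g} mg < {target:.6g} mg"
            )
        return float(brentq(lambda t: self._sol(t) - target, self.ages[0], self.ages[-1]))


def smooth_growth_curve(
    fit: Union[RateCurveFit, Sequence[float]],
    W0: float,
    n_points: int = 400,
    approach: float = 1e-6,
) -> SmoothGrowthCurve:
    """Integrate dW/dt = q(W) from ``W0`` into a smooth growth curve.

    The ultimate mass is the smallest real root of the quadratic above
    ``W0`` (the asymptote of the flow started below it).  Integration
    runs until mass reaches (1 - ``approach``) * W_U, which is always a
    finite time for a simple root.  t95 and fraction ages come from
    root-finding on the dense solution.
    """
    coef = np.asarray(fit.coef if isinstance(fit, RateCurveFit) else fit, dtype=float)
    if coef.shape != (3,):
        raise DomainError("need quadratic coefficients (c2, c1, c0)")
    if W0 <= 0:
        raise DomainError(f"W0 must be > 0, got {W0}")
    roots = np.roots(coef)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    above = real[real > W0 * (1.0 + 1e-12)]
    if len(above) == 0:
        if len(real) and math.isclose(real.max(), W0, rel_tol=1e-9):
            raise DomainError(
                f"quadratic root coincides with W0 = {W0}: degenerate zero-length curve"
            )
        raise DomainError(
            f"rate quadratic has no positive root above W0 = {W0}; "
            "no implied ultimate mass"
        )
    W_U = float(above[0])
    if np.polyval(coef, 0.5 * (W0 + W_U)) <= 0:
        raise DomainError("rate quadratic is not positive between W0 and its root")

    target = (1.0 - approach) * W_U
    event = lambda t, y: y[0] - target
    event.terminal = True
    event.direction = 1
    t_end = 100.0
    for _ in range(30):
        res = solve_ivp(
            lambda t, y: [np.polyval(coef, y[0])],
            (0.0, t_end),
            [W0],
            method="LSODA",
            dense_output=True,
            rtol=1e-9,
            atol=1e-12,
            events=[event],
        )
        if not res.success and res.status != 1:
            raise IntegrationError(f"smooth-curve integration failed: {res.message}")
        if res.status == 1:
            break
        t_end *= 2.0
    else:
        raise IntegrationError("smooth curve did not approach its asymptote")

    sol = lambda t, _s=res.sol: float(_s(t)[0])
    ages = np.linspace(0.0, res.t[-1], n_points)
    masses = np.array([sol(t) for t in ages])
    t95 = float(brentq(lambda t: sol(t) - 0.95 * W_U, 0.0, res.t[-1])) if masses[-1] >= 0.95 * W_U else math.nan
    return SmoothGrowthCurve(ages=ages, masses=masses, W_U=W_U, t95=t95, _sol=sol)


def normalized_food_availability(densities: Sequence[float]) -> np.ndarray:
    """min(log10 d) / log10 d_i for each starting density d_i.

    Yields a proxy for relative food availability in (0, 1], equal to 1
    at the smallest density of the design.  Densities must exceed 1.
    """
    d = np.asarray(densities, dtype=float)
    if np.any(d <= 1):
        raise DomainError("densities must be > 1 (log10 must be positive)")
    logs = np.log10(d)
    return logs.min() / logs


def maturation_summary(table: CohortTable) -> pd.DataFrame:
    """Mean age and mass at maturation per (starting density, sex).

    Individuals without a maturation record are ignored; sexes are never
    pooled.  Groups with no matured individuals are omitted with a
    warning.  Rows are ordered by density (then sex).
    """
    df = table.df
    if df["maturation_age"].isna().all():
        raise DomainError("no maturation records present in the table")
    per_ind = (
        df.dropna(subset=["maturation_age"])
        .groupby(["starting_density", "sex", "cohort_id", "individual_id"])
        .agg(maturation_age=("maturation_age", "first"), maturation_mass=("maturation_mass", "first"))
        .reset_index()
    )
    all_groups = df.dropna(subset=["sex"]).groupby(["starting_density", "sex"]).size()
    out = (
        per_ind.groupby(["starting_density", "sex"])
        .agg(
            mean_maturation_age=("maturation_age", "mean"),
            mean_maturation_mass=("maturation_mass", "mean"),
            n_matured=("maturation_age", "size"),
        )
        .reset_index()
        .sort_values(["starting_density", "sex"])
        .reset_index(drop=True)
    )
    present = set(map(tuple, out[["starting_density", "sex"]].to_numpy()))
    for key in all_groups.index:
        if key not in present:
            warnings.warn(f"group {key}: no matured individuals, omitted", stacklevel=2)
    return out
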