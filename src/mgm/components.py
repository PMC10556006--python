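"""Energetic component functions of the maintenance-growth model.

The growth of an individual is written as an energy balance between
ingestion, metabolic expenditure and the energy bound in new tissue:

    e*S = R_M + R_F + R_G + G

where ``S`` is the ingestion rate, ``e`` the assimilation efficiency,
``R_M`` maintenance, ``R_F`` feeding costs (foraging + digestion), and the
growth-related terms ``R_G = E_S(W) * dW/dt`` (synthesis overhead) and
``G = E_M(W) * dW/dt`` (energy bound in biomass).  This module provides the
pure component functions; the ODE assembly lives in :mod:`mgm.engine`.

Units are fixed package-wide: mass in mg, time in days, energy in J.  All
normalisation constants are documented in those units.

The distinguishing feature of the model is the split of maintenance into a
*non-negotiable* (basal) part, proportional to tissue mass, and a
*negotiable* ("defence": immune system, buffering) part that an animal
downregulates under food restriction.  The negotiable share of maintenance
is the fraction

    rho(phi, W) = a_N * W^b_N * phi^delta,   0 <= rho < 1,

so total maintenance is ``gamma_B * W / (1 - rho)``: hyperallometric in W
for ``b_N > 0`` and responsive to the relative food acquirement ``phi``
through the defence reduction exponent ``delta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .exceptions import (
    ConfigurationError,
    DomainError,
    InvalidCompositionError,
    SingularMaintenanceError,
)

__all__ = [
    "IngestionParams",
    "CompositionParams",
    "FeedingParams",
    "MaintenanceParams",
    "EnergyBudget",
    "ingestion_rate",
    "energy_density_EM",
    "growth_overhead_ES",
    "feeding_cost",
    "defence_fraction",
    "maintenance_cost",
    "power_law_fraction",
]

#: A composition fraction may be a constant or a function of body mass (mg).
MassFn = Union[float, Callable[[float], float]]

_POST_BREAK_POLICIES = ("hold-allometry", "cap-at-break-value")


def _eval(value: MassFn, W: float) -> float:
    """Evaluate a constant-or-function-of-mass field at body mass ``W``."""
    if callable(value):
        return float(value(W))
    return float(value)


def power_law_fraction(g_a: float, g_b: float) -> Callable[[float], float]:
    """Return the allometric fraction hook ``W -> min(1, g_a * W**g_b)``.

    A convenience for letting e.g. the cell-enlargement share of somatic
    growth, or the reproductive share of mass increase, rise with body
    size.  The clamp at 1 keeps the result a valid fraction.
    """
    if g_a < 0:
        raise DomainError("power-law fraction requires g_a >= 0")

    def fn(W: float) -> float:
        return min(1.0, g_a * W**g_b)

    return fn


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IngestionParams:
    """Allometric ingestion capacity S_max(W) = alpha * W**beta.

    Parameters
    ----------
    alpha :
        Normalisation constant of the maximum (ad libitum) ingestion rate,
        J * mg^-beta * day^-1.
    beta :
        Allometric exponent, dimensionless; 0 <= beta <= 1.5.
    W_break :
        Body mass (mg) where the allometry potentially breaks, e.g. when a
        determinate grower stops increasing its feeding capacity around
        maturation.  Default infinity (no break).
    post_break_policy :
        Behaviour above ``W_break``: ``"hold-allometry"`` keeps
        alpha * W**beta, ``"cap-at-break-value"`` freezes S_max at its
        value at the break mass.
    """

    alpha: float
    beta: float = 0.75
    W_break: float = math.inf
    post_break_policy: str = "hold-allometry"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if not 0.0 <= self.beta <= 1.5:
            raise DomainError(f"beta must lie in [0, 1.5], got {self.beta}")
        if self.W_break <= 0:
            raise DomainError(f"W_break must be > 0, got {self.W_break}")
        if self.post_break_policy not in _POST_BREAK_POLICIES:
            raise ConfigurationError(
                f"post_break_policy must be one of {_POST_BREAK_POLICIES}, "
                f"got {self.post_break_policy!r}"
            )

    def s_max(self, W: float) -> float:
        """Maximum ingestion rate (J/day) at body mass ``W`` (mg)."""
        if W <= 0:
            raise DomainError(f"body mass must be > 0, got {W}")
        if W <= self.W_break or self.post_break_policy == "hold-allometry":
            return self.alpha * W**self.beta
        return self.alpha * self.W_break**self.beta


def ingestion_rate(phi: float, W: float, p: IngestionParams) -> float:
    """Realised ingestion rate S = phi * S_max(W), in J/day.

    ``phi`` is the relative food acquirement: realised over ad-libitum
    ingestion at the current body size, in [0, 1].
    """
    if not 0.0 <= phi <= 1.0:
        raise DomainError(f"phi must lie in [0, 1], got {phi}")
    if W <= 0:
        raise DomainError(f"body mass must be > 0, got {W}")
    return phi * p.s_max(W)


# ---------------------------------------------------------------------------
# Tissue composition: energy density and growth overhead
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionParams:
    """Composition of newly synthesized tissue and its energetic constants.

    Energy densities (J/mg):

    - ``E_CP`` carbohydrate/protein somatic tissue (default 17),
    - ``E_L`` lipid somatic tissue (default 34),
    - ``E_MR`` reproductive tissue,
    - ``E_SSD``/``E_SSG`` specific synthesis overheads for somatic cell
      division / cell growth,
    - ``E_SR`` specific synthesis overhead for reproductive tissue.

    Fractions (constants or functions of body mass, all in [0, 1]):

    - ``f_R`` share of mass increase that is reproductive,
    - ``f_G`` share of somatic growth achieved by cell enlargement,
    - ``f_CP``/``f_L`` carbohydrate-protein and lipid shares of somatic
      growth (the remainder is water/ash with zero energy density),
    - ``p_R`` reproductive share of standing body mass.

    The defaults (f_CP = 0.29, f_L = 0.06) put the energy density of fresh
    somatic tissue at 17*0.29 + 34*0.06 = 6.97 J/mg, the canonical ~7 J/mg
    of fresh animal tissue.
    """

    E_CP: float = 17.0
    E_L: float = 34.0
    E_MR: float = 6.97
    E_SSD: float = 2.0
    E_SSG: float = 2.0
    E_SR: float = 2.0
    f_R: MassFn = 0.0
    f_G: MassFn = 0.5
    f_CP: MassFn = 0.29
    f_L: MassFn = 0.06
    p_R: MassFn = 0.0

    def __post_init__(self) -> None:
        for name in ("E_CP", "E_L", "E_MR", "E_SSD", "E_SSG", "E_SR"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    def fractions_at(self, W: float) -> dict:
        """Evaluate and validate all composition fractions at mass ``W``."""
        out = {
            name: _eval(getattr(self, name), W)
            for name in ("f_R", "f_G", "f_CP", "f_L", "p_R")
        }
        for name, value in out.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidCompositionError(
                    f"{name}({W}) = {value} lies outside [0, 1]"
                )
        if out["f_CP"] + out["f_L"] > 1.0 + 1e-12:
            raise InvalidCompositionError(
                f"f_CP + f_L = {out['f_CP'] + out['f_L']} > 1 at W = {W}"
            )
        return out


def energy_density_EM(W: float, c: CompositionParams) -> float:
    """Mass-specific energy content E_M(W) of newly synthesized tissue (J/mg).

    E_M(W) = (E_CP*f_CP + E_L*f_L) * (1 - f_R) + E_MR * f_R
    """
    f = c.fractions_at(W)
    somatic = c.E_CP * f["f_CP"] + c.E_L * f["f_L"]
    return somatic * (1.0 - f["f_R"]) + c.E_MR * f["f_R"]


def growth_overhead_ES(W: float, c: CompositionParams) -> float:
    """Specific growth overhead cost E_S(W) (J per mg of new tissue).

    E_S(W) = [E_SSD*(1 - f_G) + E_SSG*f_G] * (1 - f_R) + E_SR * f_R

    Moulting costs are not treated separately; they are absorbed into the
    somatic overhead constants.
    """
    f = c.fractions_at(W)
    somatic = c.E_SSD * (1.0 - f["f_G"]) + c.E_SSG * f["f_G"]
    return somatic * (1.0 - f["f_R"]) + c.E_SR * f["f_R"]


# ---------------------------------------------------------------------------
# Feeding costs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedingParams:
    """Metabolic costs of finding and processing food.

    The default form is proportional, ``R_F = k_F * S`` with
    ``0 <= k_F < 1``.  A custom monotone cost function of the ingestion
    rate may be supplied instead; it must vanish at S = 0 and be
    non-decreasing (validated on a log-spaced grid at construction).
    """

    k_F: float = 0.1
    custom_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.custom_fn is None:
            if not 0.0 <= self.k_F < 1.0:
                raise DomainError(f"k_F must lie in [0, 1), got {self.k_F}")
        else:
            self._validate_custom()

    def _validate_custom(self) -> None:
        fn = self.custom_fn
        if abs(fn(0.0)) > 1e-12:
            raise ConfigurationError("custom feeding-cost function must satisfy R_F(0) = 0")
        grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e6, 61)])
        values = np.array([fn(s) for s in grid])
        if np.any(np.diff(values) < -1e-12):
            raise ConfigurationError(
                "custom feeding-cost function must be non-decreasing in S"
            )


def feeding_cost(S: float, p: FeedingParams) -> float:
    """Feeding cost R_F(S) in J/day; proportional k_F*S unless overridden."""
    if S < 0:
        raise DomainError(f"ingestion rate must be >= 0, got {S}")
    if p.custom_fn is not None:
        return float(p.custom_fn(S))
    return p.k_F * S


# ---------------------------------------------------------------------------
# Maintenance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaintenanceParams:
    """Basal plus negotiable maintenance, split by tissue type.

    ``gamma_BS``/``gamma_BR`` are specific basal maintenance rates
    (J * mg^-1 * day^-1) of somatic and reproductive tissue; ``gamma_BS``
    accepts a function of body mass as a hook for cell-size-dependent
    basal costs.  ``a_NS``/``a_NR`` (mg^-b) and ``b_NS``/``b_NR``
    parameterize the ad-libitum defence allocation
    rho_N(W) = a_N * W**b_N, and ``delta`` >= 0 controls how fast defence
    is downregulated as phi falls (rho = rho_N * phi**delta).
    """

    gamma_BS: MassFn = 0.44
    gamma_BR: MassFn = 0.44
    a_NS: float = 0.001125
    a_NR: float = 0.001125
    b_NS: float = 1.0
    b_NR: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_BS", "gamma_BR"):
            v = getattr(self, name)
            if not callable(v) and v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")
        if self.a_NS < 0 or self.a_NR < 0:
            raise DomainError("a_NS and a_NR must be >= 0")
        if self.delta < 0:
            raise DomainError(f"delta must be >= 0, got {self.delta}")

    @classmethod
    def simple(
        cls,
        gamma_B: MassFn = 0.44,
        a_N: float = 0.001125,
        b_N: float = 1.0,
        delta: float = 1.0,
    ) -> "MaintenanceParams":
        """Single-tissue parameterization (somatic and reproductive alike)."""
        return cls(
            gamma_BS=gamma_B,
            gamma_BR=gamma_B,
            a_NS=a_N,
            a_NR=a_N,
            b_NS=b_N,
            b_NR=b_N,
            delta=delta,
        )

    @property
    def is_symmetric(self) -> bool:
        return (
            not callable(self.gamma_BS)
            and not callable(self.gamma_BR)
            and self.gamma_BS == self.gamma_BR
            and self.a_NS == self.a_NR
            and self.b_NS == self.b_NR
        )


def defence_fraction(
    phi: float, W_tissue: float, a_N: float, b_N: float, delta: float
) -> float:
    """Negotiable (defence) share of maintenance, rho = a_N * W**b_N * phi**delta.

    Raises :class:`SingularMaintenanceError` if rho >= 1, where total
    maintenance would diverge.
    """
    if not 0.0 <= phi <= 1.0:
        raise DomainError(f"phi must lie in [0, 1], got {phi}")
    if W_tissue < 0:
        raise DomainError(f"tissue mass must be >= 0, got {W_tissue}")
    rho = a_N * W_tissue**b_N * phi**delta
    if rho >= 1.0:
        raise SingularMaintenanceError(
            f"defence fraction rho = {rho:.6g} >= 1 at tissue mass "
            f"{W_tissue:.6g} mg (phi = {phi}); maintenance diverges"
        )
    return rho


def maintenance_cost(
    phi: float, W: float, m: MaintenanceParams, p_R: float = 0.0
) -> float:
    """Total maintenance R_M(phi, W) in J/day.

    Two-tissue form: each tissue contributes
    gamma_B * W_tissue / (1 - rho(phi, W_tissue)), with W_S = (1-p_R)*W and
    W_R = p_R*W.  With identical tissue parameters, or p_R = 0, this
    reduces exactly to the lumped single-tissue form
    gamma_B * W / (1 - a_N * W**b_N * phi**delta).
    """
    if W <= 0:
        raise DomainError(f"body mass must be > 0, got {W}")
    if not 0.0 <= p_R <= 1.0:
        raise DomainError(f"p_R must lie in [0, 1], got {p_R}")
    total = 0.0
    tissues = (
        (m.gamma_BS, (1.0 - p_R) * W, m.a_NS, m.b_NS),
        (m.gamma_BR, p_R * W, m.a_NR, m.b_NR),
    )
    for gamma, W_t, a_N, b_N in tissues:
        if W_t == 0.0:
            continue
        rho = defence_fraction(phi, W_t, a_N, b_N, m.delta)
        gamma_v = _eval(gamma, W_t)
        total += gamma_v * W_t / (1.0 - rho)
    return total


# ---------------------------------------------------------------------------
# Energy budget record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyBudget:
    """Instantaneous energy-budget decomposition at one state (J/day).

    ``residual`` is e*S - R_M - R_F - R_G - G, which is identically zero
    up to floating-point rounding because the growth rate is defined by
    that very balance.  Losses (egestion + excretion) are the implicit
    (1 - e)*S and are not stored separately.
    """

    age: float
    W: float
    S: float
    assimilated: float
    R_M: float
    R_F: float
    R_G: float
    G: float
    residual: float

    @property
    def R_tot(self) -> float:
        return self.R_M + self.R_F + self.R_G
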