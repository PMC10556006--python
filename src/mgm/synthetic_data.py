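"""Seeded generator of synthetic cricket-like cohort tables.

The generator emulates a self-thinning experiment: cohorts of starting
densities 5-80 newly hatched nymphs (~0.67 mg) share a fixed food
supply, so higher densities experience stronger food restriction.
Restriction is imposed, not emergent: each density maps to a fixed
relative food acquirement phi, by default the normalised food
availability min(log10 d)/log10 d of the design, which is 1 at the
lowest density and ~0.37 at density 80.

Each individual carries a multiplicative lognormal scale factor (mean
1) applied to the deterministic trajectory of its density — a simple
stand-in for among-individual variation in size — and every
measurement gets independent multiplicative lognormal noise.  Optional
constant per-day mortality thins later samples; a fixed mass threshold
emits maturation records.  Identical seeds reproduce tables exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort_data import COHORT_COLUMNS, CohortTable
from .engine import ModelParams, integrate_growth
from .exceptions import ConfigurationError, DomainError
from .presets import W0_CRICKET, cricket_params

__all__ = ["SyntheticConfig", "generate_cohort", "density_phi_map"]


def density_phi_map(densities: Sequence[int]) -> Dict[int, float]:
    """Default density -> phi mapping: normalised food availability."""
    d = np.asarray(densities, dtype=float)
    logs = np.log10(d)
    return {int(di): float(logs.min() / math.log10(di)) for di in densities}


@dataclass
class SyntheticConfig:
    """Study design of a synthetic cohort experiment.

    Defaults mirror the emulated experiment: densities {5, 10, 20, 40,
    80}, hatchling mass 0.67 mg, weekly sampling over 20 weeks, 10%
    among-individual scale variation, 3% measurement noise, a mild
    constant mortality hazard, and maturation at a 50 mg threshold
    (chosen so that maturation occurs across the whole density range of
    the emulated design).
    """

    params: ModelParams = field(default_factory=cricket_params)
    densities: Sequence[int] = (5, 10, 20, 40, 80)
    phi_of_density: Optional[Mapping[int, float]] = None
    W0_mean: float = W0_CRICKET
    individual_cv: float = 0.10
    measurement_cv: float = 0.03
    sampling_ages: Sequence[float] = tuple(range(0, 141, 7))
    mortality_rate: float = 0.005
    maturation_mass: Optional[float] = 50.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individual_cv < 0 or self.measurement_cv < 0:
            raise DomainError("coefficients of variation must be >= 0")
        if self.W0_mean <= 0:
            raise DomainError("W0_mean must be > 0")
        if self.mortality_rate < 0:
            raise DomainError("mortality_rate must be >= 0")
        ages = np.asarray(self.sampling_ages, dtype=float)
        if len(ages) < 2 or np.any(np.diff(ages) <= 0):
            raise DomainError("sampling_ages must be >= 2 strictly increasing ages")

    def phi_for(self, density: int) -> float:
        mapping = self.phi_of_density
        if mapping is None:
            mapping = density_phi_map(self.densities)
        try:
            phi = float(mapping[density])
        except KeyError:
            raise ConfigurationError(
                f"phi_of_density has no entry for density {density}"
            ) from None
        if not 0.0 < phi <= 1.0:
            raise ConfigurationError(f"phi({density}) = {phi} must lie in (0, 1]")
        return phi


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def generate_cohort(cfg: SyntheticConfig) -> CohortTable:
    """Generate a cohort table under the configured study design.

    For each density the true model is integrated once at phi(density);
    each individual's noiseless curve is that trajectory times its
    lognormal scale factor, sampled at the configured ages with
    measurement noise, thinned by an exponential death age when a
    mortality hazard is set.  A maturation record (age found by
    root-finding on the scaled noiseless curve, mass equal to the
    threshold) is emitted for individuals whose curve crosses the
    threshold before death.
    """
    rng = np.random.default_rng(cfg.seed)
    ages = np.asarray(cfg.sampling_ages, dtype=float)
    t_end = float(ages[-1])
    rows = []
    for density in cfg.densities:
        phi = cfg.phi_for(density)
        traj = integrate_growth(cfg.W0_mean, t_end, cfg.params, phi, ages=ages)
        base = traj.masses
        for rep in range(cfg.n_replicates):
            cohort_id = f"d{density}r{rep + 1}"
            for ind in range(1, int(density) + 1):
                scale = float(_lognormal_factor(rng, cfg.individual_cv))
                if cfg.mortality_rate > 0:
                    death_age = float(rng.exponential(1.0 / cfg.mortality_rate))
                else:
                    death_age = math.inf
                sex = str(rng.choice(["F", "M"]))
                noise = _lognormal_factor(rng, cfg.measurement_cv, size=len(ages))

                mat_age = mat_mass = np.nan
                if cfg.maturation_mass is not None:
                    threshold = cfg.maturation_mass
                    curve = lambda t: scale * traj.mass_at(t) - threshold
                    if scale * base[0] >= threshold:
                        mat_age, mat_mass = 0.0, scale * base[0]
                    elif scale * base[-1] >= threshold:
                        t_cross = brentq(curve, 0.0, t_end, xtol=1e-9)
                        if t_cross <= death_age:
                            mat_age, mat_mass = float(t_cross), float(threshold)

                alive = ages <= death_age
                alive[0] = True  # the starting census always exists
                for t, m0, eps, keep in zip(ages, base, noise, alive):
                    if not keep:
                        break
                    rows.append(
                        {
                            "cohort_id": cohort_id,
                            "starting_density": int(density),
                            "individual_id": f"{cohort_id}i{ind:03d}",
                            "age": float(t),
                            "mass": float(scale * m0 * eps),
                            "sex": sex,
                            "maturation_age": mat_age,
                            "maturation_mass": mat_mass,
                        }
                    )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return CohortTable(df)
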