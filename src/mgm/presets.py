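"""Reference parameter sets.

The package-default parameter set emulates a house cricket (*Acheta
domesticus*) growing from a newly hatched nymph of ~0.67 mg to an
asymptotic mass of ~400 mg over a couple of months at 28-30 C.  The
component values are package choices, documented in docs/methods.md;
the energy densities of carbohydrate/protein (17 J/mg) and lipid
(34 J/mg) tissue are literature constants.
"""

from __future__ import annotations

from .components import (
    CompositionParams,
    FeedingParams,
    IngestionParams,
    MaintenanceParams,
)
from .engine import ModelParams

__all__ = ["cricket_params", "reduced_params", "W0_CRICKET"]

#: Starting body mass of a newly hatched cricket nymph (mg).
W0_CRICKET = 0.67


def cricket_params(
    b_N: float = 1.0,
    a_N: float | None = None,
    delta: float = 1.0,
) -> ModelParams:
    """Default cricket-like parameter set.

    With the default ``b_N = 1`` the defence allocation rises linearly
    with mass (a_N = 0.001125 per mg puts the ad-libitum defence share at
    0.45 near the asymptote of ~400 mg), producing the hyperallometric
    maintenance that shifts the growth-rate hump past the reach of
    supply-minus-expenditure power-law models.  ``b_N = 0`` selects the
    mass-independent defence share (a_N defaults to 0.15, dimensionless),
    the regime equivalent to a von Bertalanffy equation at fixed phi.
    """
    if a_N is None:
        a_N = 0.001125 if b_N != 0.0 else 0.15
    return ModelParams(
        ingestion=IngestionParams(alpha=5.13, beta=0.75),
        composition=CompositionParams(),
        feeding=FeedingParams(k_F=0.1),
        maintenance=MaintenanceParams.simple(
            gamma_B=0.44, a_N=a_N, b_N=b_N, delta=delta
        ),
        e=0.8,
        variant="simplified",
    )


def reduced_params(
    a: float,
    beta: float,
    c: float = 0.0,
    a_N: float = 0.0,
    b_N: float = 1.0,
    delta: float = 1.0,
) -> ModelParams:
    """Build component parameters realizing the reduced ad-libitum rate

        dW/dt = a*W**beta - c*W / (1 - a_N*W**b_N)

    exactly (at phi = 1), by choosing unit combined energy density
    (E_M + E_S = 1), k_F = 0, e = 1/2 and alpha = 2a (both exact in
    binary floating point, so the reduced coefficients are reproduced to
    the last bit).  Intended for tests and for mapping fitted reduced
    coefficients back onto the component machinery.
    """
    comp = CompositionParams(
        E_CP=1.0, E_L=0.0, E_MR=1.0,
        E_SSD=0.0, E_SSG=0.0, E_SR=0.0,
        f_CP=1.0, f_L=0.0,
    )
    return ModelParams(
        ingestion=IngestionParams(alpha=2.0 * a, beta=beta),
        composition=comp,
        feeding=FeedingParams(k_F=0.0),
        maintenance=MaintenanceParams.simple(
            gamma_B=c, a_N=a_N, b_N=b_N, delta=delta
        ),
        e=0.5,
        variant="simplified",
    )
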