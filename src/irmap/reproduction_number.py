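"""Basic reproduction number of insecticide resistance.

R0 is the average number of resistant mosquitoes a single resistant
mosquito gives rise to over its lifetime; resistance spreads through the
population when R0 > 1 and dies out when R0 < 1.  The closed form is

    R0 = 1/(mu + mu_i + alpha) * sqrt(beta * (r + gamma) / N)

and the climate-driven form substitutes the temperature-dependent
mortality mu(T) and the rainfall/temperature birth rate r(R, T) into it.

``ngm_standard`` is a diagnostic: the spectral radius of the standard
next-generation matrix F.V^-1 built on the infected compartments {R, M}
of the imperfect-transmission model.  It does NOT reproduce the closed
form above — the two constructions disagree — and is exposed only so
the discrepancy is measurable.  The closed form is authoritative for
all maps and sensitivity results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

from .climate_response import (
    INVALID,
    ClimateSample,
    LifeHistoryParameters,
    birth_rate,
    is_invalid,
    mortality_rate,
)
from .model_core import ModelParameters, invasion_conditions

__all__ = [
    "R0Value",
    "RiskClass",
    "MODERATE_LOW",
    "MODERATE_HIGH",
    "r0_formula",
    "r0_closed_form",
    "r0_climate",
    "r0_climate_expanded",
    "classify_risk",
    "ngm_standard",
]

#: risk-class thresholds: low < 1, moderate in [1, 1.1] (closed interval),
#: high > 1.1
MODERATE_LOW = 1.0
MODERATE_HIGH = 1.1


class RiskClass(IntEnum):
    """Map legend classes; integer values are the raster class codes."""

    NODATA = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


@dataclass(frozen=True)
class R0Value:
    """An R0 evaluation together with the inputs that produced it."""

    value: float
    inputs_echo: object = None

    @property
    def valid(self) -> bool:
        return not is_invalid(self.value)


def r0_formula(
    r: float, beta: float, gamma: float, alpha: float, mu: float, mu_i: float, N: float
) -> float:
    """The closed-form arithmetic on raw values.

    Used directly by sensitivity perturbations, where a formally
    perturbed probability (e.g. beta = 1.1) is a sensitivity construct
    rather than a biological parameter set.
    """
    denom = mu + mu_i + alpha
    if denom == 0:
        raise ZeroDivisionError("R0 undefined: mu + mu_i + alpha == 0")
    return math.sqrt(beta * (r + gamma) / N) / denom


def r0_closed_form(params: ModelParameters) -> R0Value:
    """Closed-form R0 = sqrt(beta*(r+gamma)/N) / (mu + mu_i + alpha)."""
    value = r0_formula(
        params.r, params.beta, params.gamma, params.alpha, params.mu, params.mu_i, params.N
    )
    return R0Value(value=value, inputs_echo=params)


def r0_climate(
    sample: ClimateSample,
    params: ModelParameters,
    lh: LifeHistoryParameters,
) -> R0Value:
    """Climate-driven R0: the closed form with r <- r(R,T), mu <- mu(T).

    Invalid where mu(T) is undefined (lifespan polynomial <= 0); the
    invalid marker propagates so raster maps carry the cell as nodata.
    """
    mu = mortality_rate(sample.T, lh)
    if is_invalid(mu):
        return R0Value(value=INVALID, inputs_echo=sample)
    r = birth_rate(sample, lh)
    if is_invalid(r):
        return R0Value(value=INVALID, inputs_echo=sample)
    value = r0_closed_form(params.replace(r=r, mu=mu)).value
    return R0Value(value=value, inputs_echo=sample)


def r0_climate_expanded(
    sample: ClimateSample,
    params: ModelParameters,
    lh: LifeHistoryParameters,
) -> R0Value:
    """Single-expression form of the climate-driven R0.

    Algebraically identical to :func:`r0_climate` (the mortality
    polynomial is pulled inside the square root); kept as an independent
    route for cross-checking the substitution.
    """
    T, R = sample.T, sample.rain
    poly = lh.a * T * T + lh.b * T + lh.c
    if poly <= 0:
        return R0Value(value=INVALID, inputs_echo=sample)
    x = lh.k1 * T + lh.k2
    dev_denom = 2.0 * x + 1.0
    if dev_denom <= 0:
        return R0Value(value=INVALID, inputs_echo=sample)
    rf = (4.0 * R * (lh.R_L - R) / (lh.R_L * lh.R_L)) ** 3 if R < lh.R_L else 0.0
    r = lh.B_E * lh.theta_E * lh.theta_L * lh.theta_P * rf * x * math.exp(-x) / dev_denom
    r = max(r, 0.0)
    value = math.sqrt(
        params.beta * (r + params.gamma) * poly * poly
        / (params.N * (poly * (params.mu_i + params.alpha) + 1.0) ** 2)
    )
    return R0Value(value=value, inputs_echo=sample)


def classify_risk(r0: R0Value | float) -> RiskClass:
    """Risk class of an R0 value: low (<1), moderate ([1, 1.1]), high (>1.1).

    The moderate band is the closed interval, so exactly 1 and exactly
    1.1 are moderate.  Invalid R0 maps to the nodata class.
    """
    value = r0.value if isinstance(r0, R0Value) else float(r0)
    if is_invalid(value):
        return RiskClass.NODATA
    if value < MODERATE_LOW:
        return RiskClass.LOW
    if value <= MODERATE_HIGH:
        return RiskClass.MODERATE
    return RiskClass.HIGH


def ngm_standard(params: ModelParameters) -> float:
    """Spectral radius of the standard next-generation matrix (diagnostic).

    At the resistance-free equilibrium the infected block {R, M} of the
    imperfect-transmission model decouples, so F.V^-1 is diagonal with
    entries ``beta*S0/(N*mu)`` and ``(gamma-alpha)*S0/mu``; the spectral
    radius is their maximum.  This construction does not coincide with
    the closed-form R0 used for mapping; it agrees with the invasion
    thresholds of the linearized system instead.
    """
    return max(invasion_conditions(params))
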