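"""Temperature and rainfall responses of Anopheles gambiae life history.

Adult mortality follows the Martens-style temperature polynomial: the
expected adult lifespan (days) is the quadratic ``a*T^2 + b*T + c`` and
the daily mortality rate its reciprocal.  Where the quadratic is not
positive the mortality rate is undefined and the invalid marker (NaN) is
returned, so raster pipelines can carry the cell as nodata instead of
aborting.

The birth rate combines egg production and immature survival with a
rainfall-driven breeding-site factor peaking at half the rainfall limit
``R_L``, and a temperature-dependent development term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LifeHistoryParameters",
    "ClimateSample",
    "INVALID",
    "is_invalid",
    "mortality_rate",
    "rainfall_factor",
    "birth_rate",
]

#: marker for "undefined at this climate" — a value, not an exception,
#: so per-pixel maps propagate it as nodata
INVALID = float("nan")


def is_invalid(x: float) -> bool:
    """True if *x* is the invalid-climate marker."""
    return math.isnan(x)


@dataclass(frozen=True)
class LifeHistoryParameters:
    """Life-history constants feeding the climate-driven rates.

    Parameters
    ----------
    B_E : float
        Eggs per oviposition.
    theta_E, theta_L, theta_P : float
        Daily survival probabilities of egg, larva and pupa, in [0, 1].
    R_L : float
        Rainfall limit (mm/month) beyond which breeding sites wash out;
        the oviposition factor peaks at ``R_L / 2``.
    k1 : float
        Development constant ((degC day)^-1).
    k2 : float
        Development constant (day^-1).
    a, b, c : float
        Coefficients of the lifespan quadratic ``a*T^2 + b*T + c`` in
        (degC^2 day)^-1, (degC day)^-1 and day^-1.
    """

    B_E: float
    theta_E: float
    theta_L: float
    theta_P: float
    R_L: float
    k1: float
    k2: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.B_E <= 0:
            raise ValueError(f"B_E must be > 0, got {self.B_E!r}")
        if self.R_L <= 0:
            raise ValueError(f"R_L must be > 0, got {self.R_L!r}")
        for name in ("theta_E", "theta_L", "theta_P"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class ClimateSample:
    """One (temperature, rainfall) forcing sample.

    T is the monthly mean temperature in degC; rain is the monthly
    rainfall total in mm, treated as the representative daily forcing
    for that month.
    """

    T: float
    rain: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.T):
            raise ValueError(f"T must be finite, got {self.T!r}")
        if self.rain < 0:
            raise ValueError(f"rain must be >= 0, got {self.rain!r}")


def mortality_rate(T: float, lh: LifeHistoryParameters) -> float:
    """Daily adult mortality mu(T) = 1 / (a*T^2 + b*T + c).

    Returns the invalid marker where the lifespan quadratic is <= 0
    (mortality undefined; treat the cell as nodata downstream).
    """
    if not math.isfinite(T):
        return INVALID
    lifespan = lh.a * T * T + lh.b * T + lh.c
    if lifespan <= 0:
        return INVALID
    return 1.0 / lifespan


def rainfall_factor(rain: float, R_L: float) -> float:
    """Breeding-site availability factor in [0, 1].

    ``(4 * rain * (R_L - rain) / R_L**2) ** 3`` — a cubed parabola that
    vanishes at zero rainfall, peaks at ``R_L / 2`` and collapses back to
    zero at the rainfall limit.  Rainfall above ``R_L`` floods breeding
    sites; the factor is clamped to 0 there rather than going negative.
    """
    if R_L <= 0:
        raise ValueError(f"R_L must be > 0, got {R_L!r}")
    if rain < 0:
        raise ValueError(f"rain must be >= 0, got {rain!r}")
    if rain >= R_L:
        return 0.0
    return (4.0 * rain * (R_L - rain) / (R_L * R_L)) ** 3


def birth_rate(sample: ClimateSample, lh: LifeHistoryParameters) -> float:
    """Climate-driven mosquito birth rate r(R, T) in day^-1.

    B_E * theta_E * theta_L * theta_P * rainfall_factor(R)
        * (k1*T + k2) * exp(-(k1*T + k2)) / (2*(k1*T + k2) + 1)

    floored at zero (a negative development term means no recruitment,
    not a death process).  Returns the invalid marker if the denominator
    ``2*(k1*T + k2) + 1`` is <= 0.
    """
    x = lh.k1 * sample.T + lh.k2
    denom = 2.0 * x + 1.0
    if denom <= 0:
        return INVALID
    rf = rainfall_factor(sample.rain, lh.R_L)
    r = lh.B_E * lh.theta_E * lh.theta_L * lh.theta_P * rf * x * math.exp(-x) / denom
    return max(r, 0.0)
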