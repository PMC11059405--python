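"""Compartmental dynamics of insecticide resistance in a mosquito population.

Two coupled ODE systems describe the flow between susceptible mosquitoes
(S), insecticide-resistant mosquitoes (R) and the non-resistant offspring
of resistant mosquitoes (M).  Model 1 allows imperfect vertical
transmission: non-resistant offspring re-enter the susceptible pool at
rate ``alpha``.  Model 2 is the perfect-transmission limit, identical to
model 1 with ``alpha = 0``.

Model 1::

    dS/dt = r - (mu + mu_i) S - (beta/N) S R - gamma S M + alpha M S
    dR/dt = (beta/N) S R - mu R
    dM/dt = gamma S M - alpha M S - mu M

The resistance-free equilibrium (RFE) is ``(r/(mu + mu_i), 0, 0)``:
with no resistant mosquitoes and no offspring the susceptible pool
balances births against total mortality.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "CompartmentState",
    "Trajectory",
    "rhs_model1",
    "rhs_model2",
    "resistance_free_equilibrium",
    "simulate",
    "invasion_conditions",
]

#: integrator tolerances; dynamics are non-stiff at realistic magnitudes
#: and tight tolerances keep equilibrium tests crisp
RTOL = 1e-8
ATOL = 1e-10

#: undershoot beyond this is an integrator failure, within it a rounding
#: artefact on count-valued compartments
NEGATIVE_TOL = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """The seven dynamical parameters of the resistance-transmission model.

    Parameters
    ----------
    r : float
        Mosquito birth rate (day^-1).
    beta : float
        Probability that a susceptible mosquito becomes resistant per
        contact with a resistant one under insecticide pressure
        (dimensionless, <= 1).
    gamma : float
        Probability that a resistant mosquito produces non-resistant
        offspring (dimensionless, <= 1).
    alpha : float
        Rate at which non-resistant offspring become susceptible again
        (day^-1); 0 in the perfect-transmission model.
    mu : float
        Natural death rate (day^-1).
    mu_i : float
        Insecticide-induced mortality rate (day^-1).
    N : float
        Total mosquito population size.
    """

    r: float
    beta: float
    gamma: float
    alpha: float
    mu: float
    mu_i: float
    N: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if self.N <= 0:
            raise ValueError(f"N must be > 0, got {self.N!r}")
        if self.beta > 1:
            raise ValueError(f"beta is a probability, got {self.beta!r} > 1")
        if self.gamma > 1:
            raise ValueError(f"gamma is a probability, got {self.gamma!r} > 1")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return ModelParameters(**kwargs)


@dataclass(frozen=True)
class CompartmentState:
    """Population state (S, R, M), all non-negative counts."""

    S: float
    R: float
    M: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.R, self.M], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Time-sampled solution of the ODE system."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3), columns S, R, M

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def M(self) -> np.ndarray:
        return self.states[:, 2]

    def state_at(self, i: int) -> CompartmentState:
        return CompartmentState(*self.states[i])

    def to_frame(self):
        """Trajectory as a DataFrame with columns time, S, R, M."""
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "S": self.S, "R": self.R, "M": self.M}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_state(state: CompartmentState) -> None:
    arr = state.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state contains non-finite values: {state}")


def rhs_model1(
    state: CompartmentState, params: ModelParameters
) -> tuple[float, float, float]:
    """Right-hand side of the imperfect-transmission system (model 1)."""
    _check_state(state)
    S, R, M = state.S, state.R, state.M
    p = params
    dS = p.r - (p.mu + p.mu_i) * S - (p.beta / p.N) * S * R - p.gamma * S * M + p.alpha * M * S
    dR = (p.beta / p.N) * S * R - p.mu * R
    dM = p.gamma * S * M - p.alpha * M * S - p.mu * M
    return (dS, dR, dM)


def rhs_model2(
    state: CompartmentState, params: ModelParameters
) -> tuple[float, float, float]:
    """Right-hand side of the perfect-transmission system (model 2).

    Identical to model 1 with ``alpha`` forced to zero; the ``alpha``
    field of *params* is ignored.
    """
    return rhs_model1(state, params.replace(alpha=0.0))


def resistance_free_equilibrium(params: ModelParameters) -> CompartmentState:
    """The stationary state with no resistant mosquitoes.

    S* = r / (mu + mu_i), R* = M* = 0.
    """
    denom = params.mu + params.mu_i
    if denom == 0:
        raise ZeroDivisionError(
            "resistance-free equilibrium undefined: mu + mu_i == 0"
        )
    return CompartmentState(params.r / denom, 0.0, 0.0)


def invasion_conditions(params: ModelParameters) -> tuple[float, float]:
    """Invasion threshold ratios for R and M at the resistance-free equilibrium.

    Linearizing the system at the RFE decouples R and M:

        dR/dt ~ ((beta/N) S* - mu) R
        dM/dt ~ ((gamma - alpha) S* - mu) M

    so R invades iff ``beta*S*/(N*mu) > 1`` and M invades iff
    ``(gamma - alpha)*S*/mu > 1``.  Returns the pair of ratios.
    """
    if params.mu == 0:
        raise ZeroDivisionError("invasion ratios undefined for mu == 0")
    S0 = resistance_free_equilibrium(params).S
    ratio_R = params.beta * S0 / (params.N * params.mu)
    ratio_M = (params.gamma - params.alpha) * S0 / params.mu
    return (ratio_R, ratio_M)


def simulate(
    params: ModelParameters,
    state0: CompartmentState,
    t_end: float,
    dt_out: float,
    model: int = 1,
) -> Trajectory:
    """Integrate the chosen model and sample the solution every *dt_out* days.

    Parameters
    ----------
    model : {1, 2}
        Which system to integrate; explicit, never inferred from
        ``params.alpha``.

    Raises
    ------
    RuntimeError
        If the adaptive integrator fails, carrying the failing time.
    ValueError
        If a compartment undershoots zero beyond numerical tolerance.
    """
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model!r}")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    y0 = state0.as_array()
    if np.any(y0 < 0):
        raise ValueError(f"initial state must be non-negative, got {state0}")

    p = params if model == 1 else params.replace(alpha=0.0)

    def f(t: float, y: np.ndarray) -> list[float]:
        return list(rhs_model1(CompartmentState(*y), p))

    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(
        f, (0.0, t_end), y0, method="RK45", t_eval=t_eval, rtol=RTOL, atol=ATOL
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"integration failed at t={t_fail}: {sol.message}")

    states = sol.y.T.copy()
    undershoot = states.min()
    if undershoot < -NEGATIVE_TOL:
        raise ValueError(
            f"compartment undershot zero by {-undershoot:g} (tolerance {NEGATIVE_TOL:g})"
        )
    if undershoot < 0:
        warnings.warn(
            f"clipping negative undershoot of {-undershoot:g} to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        states = np.clip(states, 0.0, None)
    return Trajectory(times=sol.t, states=states)
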