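"""Local and global sensitivity of R0 to the model parameters.

Local analysis perturbs one parameter at a time by a signed fraction
(typically +/-10%) and reports the signed percent change in the
closed-form R0.  Because R0 is a pure power law in beta and N, those
two changes are parameter-independent: +10% in beta always gives
sqrt(1.1) - 1 = +4.88%, +10% in N gives 1/sqrt(1.1) - 1 = -4.65%.

Global analysis draws a Latin hypercube over parameter ranges and
computes partial rank correlation coefficients (PRCC): Spearman-type
partial correlations between each parameter and the output, controlling
for all other parameters, with a t-based significance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import qmc

from dataclasses import asdict

from .model_core import ModelParameters
from .reproduction_number import r0_closed_form, r0_formula

__all__ = [
    "PARAMETER_NAMES",
    "PerturbationResult",
    "PRCCResult",
    "perturb_r0",
    "perturbation_table",
    "lhs_sample",
    "prcc",
    "prcc_of_r0",
    "tornado_plot",
]

PARAMETER_NAMES = ("r", "beta", "gamma", "alpha", "mu", "mu_i", "N")


@dataclass(frozen=True)
class PerturbationResult:
    """Signed percent change in R0 from a one-at-a-time perturbation."""

    parameter: str
    delta: float  # signed fraction applied, e.g. +0.10
    r0_base: float
    r0_perturbed: float
    percent_change: float  # 100 * (perturbed - base) / base


@dataclass(frozen=True)
class PRCCResult:
    """Partial rank correlation of one parameter with the output."""

    parameter: str
    prcc: float
    p_value: float
    n_samples: int
    seed: int | None = None


def perturb_r0(
    params: ModelParameters, which: str, delta: float
) -> PerturbationResult:
    """Multiply parameter *which* by ``(1 + delta)`` and recompute R0.

    Returns the signed percent change ``100 * (R0_new - R0_base) / R0_base``.
    """
    if which not in PARAMETER_NAMES:
        raise KeyError(
            f"unknown parameter {which!r}; expected one of {PARAMETER_NAMES}"
        )
    base = r0_closed_form(params).value
    if base <= 0:
        raise ValueError("baseline R0 must be > 0 for a percent change")
    # evaluate on raw values: a formally perturbed probability (beta ->
    # 1.1) is a sensitivity construct, not a biological parameter set
    raw = asdict(params)
    raw[which] = raw[which] * (1.0 + delta)
    perturbed = r0_formula(**raw)
    return PerturbationResult(
        parameter=which,
        delta=delta,
        r0_base=base,
        r0_perturbed=perturbed,
        percent_change=100.0 * (perturbed - base) / base,
    )


def perturbation_table(
    params: ModelParameters, delta: float = 0.10
) -> list[PerturbationResult]:
    """One-at-a-time +/-delta perturbations for every parameter."""
    out = []
    for name in PARAMETER_NAMES:
        out.append(perturb_r0(params, name, +delta))
        out.append(perturb_r0(params, name, -delta))
    return out


def lhs_sample(
    ranges: dict[str, tuple[float, float]], n: int, seed: int
) -> np.ndarray:
    """Latin hypercube sample: one draw per equal-width stratum per parameter.

    Parameters
    ----------
    ranges : dict
        Ordered mapping of parameter name to (low, high) bounds.
    n : int
        Number of samples (>= 10); also the number of strata.
    seed : int
        RNG seed; identical seeds give identical matrices.

    Returns
    -------
    ndarray of shape (n, len(ranges)), columns in dict order.
    """
    if n < 10:
        raise ValueError(f"n must be >= 10, got {n}")
    names = list(ranges)
    lows = np.array([ranges[k][0] for k in names], dtype=float)
    highs = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(lows >= highs):
        bad = [k for k in names if ranges[k][0] >= ranges[k][1]]
        raise ValueError(f"degenerate range for {bad}: low must be < high")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, lows, highs)


def _rank_residuals(ranks: np.ndarray, covariate_ranks: np.ndarray) -> np.ndarray:
    """Residuals of an OLS fit of *ranks* on *covariate_ranks* + intercept."""
    design = np.column_stack([np.ones(len(ranks)), covariate_ranks])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ coef


def prcc(
    samples: np.ndarray,
    outputs: np.ndarray,
    names: list[str] | None = None,
    seed: int | None = None,
) -> list[PRCCResult]:
    """Partial rank correlation coefficient of each column with *outputs*.

    All columns and the output are rank-transformed; for each parameter
    the ranks of the parameter and of the output are each regressed on
    the ranks of all other parameters, and the PRCC is the Pearson
    correlation of the two residual vectors.  Significance is a
    two-sided t test with ``n - 2 - k`` degrees of freedom, where k is
    the number of controlled covariates.
    """
    samples = np.asarray(samples, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    n, d = samples.shape
    if len(outputs) != n:
        raise ValueError("outputs length must match number of sample rows")
    if names is None:
        names = [f"x{i}" for i in range(d)]
    for j, name in enumerate(names):
        if np.ptp(samples[:, j]) == 0:
            raise ValueError(f"column {name!r} is constant; PRCC undefined")
    if np.ptp(outputs) == 0:
        raise ValueError("outputs are constant; PRCC undefined")

    rank_x = np.column_stack(
        [stats.rankdata(samples[:, j]) for j in range(d)]
    )
    rank_y = stats.rankdata(outputs)

    k = d - 1  # covariates controlled for
    dof = n - 2 - k
    results = []
    for j in range(d):
        others = np.delete(rank_x, j, axis=1)
        res_x = _rank_residuals(rank_x[:, j], others)
        res_y = _rank_residuals(rank_y, others)
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        if denom == 0:
            raise ValueError(
                f"column {names[j]!r} is rank-degenerate after controlling "
                "for the other parameters"
            )
        rho = float(np.dot(res_x, res_y) / denom)
        rho = min(1.0, max(-1.0, rho))
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt(dof / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), dof))
        results.append(
            PRCCResult(parameter=names[j], prcc=rho, p_value=p, n_samples=n, seed=seed)
        )
    return results


def default_ranges(
    params: ModelParameters, spread: float = 0.20
) -> dict[str, tuple[float, float]]:
    """Uniform +/-spread ranges around a baseline parameter set."""
    return {
        name: (getattr(params, name) * (1 - spread), getattr(params, name) * (1 + spread))
        for name in PARAMETER_NAMES
    }


def prcc_of_r0(
    params: ModelParameters,
    n: int = 1000,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[PRCCResult]:
    """Global PRCC of the closed-form R0 over an LHS of all 7 parameters.

    Default ranges are uniform +/-20% around *params*.
    """
    if ranges is None:
        ranges = default_ranges(params)
    samples = lhs_sample(ranges, n, seed)
    names = list(ranges)
    baseline = asdict(params)
    outputs = np.empty(n)
    for i, row in enumerate(samples):
        raw = dict(baseline)
        raw.update(zip(names, row))
        outputs[i] = r0_formula(**raw)
    return prcc(samples, outputs, names=names, seed=seed)


def tornado_plot(results: list[PRCCResult], path=None):
    """Horizontal bar (tornado) plot of PRCC values, largest magnitude on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(results, key=lambda r: abs(r.prcc))
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(ordered) + 1.5))
    ax.barh(
        [r.parameter for r in ordered],
        [r.prcc for r in ordered],
        color=["tab:red" if r.prcc < 0 else "tab:blue" for r in ordered],
    )
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("PRCC with $R_0$")
    ax.set_xlim(-1, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
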