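"""Cumulative-Gaussian psychometric fitting.

The psychometric function is the probability of answering "second" as a
function of the signed contrast difference dC, modelled as

    P(dC) = H((dC + b) / sigma)

with H the standard normal CDF, b the bias and sigma the internal noise
(both in contrast-percent units). Sensitivity is summarised by the maximum
slope s = 1 / sqrt(2 * pi * sigma^2): a steeper slope means a smaller sigma
and better discriminability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .sim_experiment import FIRST, SECOND, TrialRecord

__all__ = [
    "PsychometricFit",
    "BinnedChoices",
    "bin_choices",
    "fit_psychometric",
    "slope_from_sigma",
    "sigma_from_slope",
    "psychometric",
]

SIGMA_BOUNDS = (0.1, 100.0)  # contrast-percent search window
BIAS_BOUNDS = (-50.0, 50.0)


def psychometric(delta_c: np.ndarray | float, bias_b: float, sigma: float) -> np.ndarray:
    """P(answer "second") at contrast difference ``delta_c``."""
    return stats.norm.cdf((np.asarray(delta_c, dtype=float) + bias_b) / sigma)


def slope_from_sigma(sigma: float) -> float:
    """Maximum slope s = 1/sqrt(2*pi*sigma^2); strictly decreasing in sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    return 1.0 / math.sqrt(2.0 * math.pi * sigma * sigma)


def sigma_from_slope(slope: float) -> float:
    """Inverse of :func:`slope_from_sigma`."""
    if slope <= 0:
        raise ValueError("slope must be strictly positive")
    return 1.0 / (math.sqrt(2.0 * math.pi) * slope)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted (b, sigma) pair with the derived sensitivity slope."""

    bias_b: float
    sigma: float
    n_trials: int
    fit_method: str = "least_squares"
    converged: bool = True
    slope_s: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be strictly positive")
        object.__setattr__(self, "slope_s", slope_from_sigma(self.sigma))

    def predict(self, delta_c: np.ndarray | float) -> np.ndarray:
        return psychometric(delta_c, self.bias_b, self.sigma)


@dataclass(frozen=True)
class BinnedChoices:
    """Per-level counts of "second" answers."""

    delta_c_levels: np.ndarray
    n_second: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.delta_c_levels, dtype=float)
        if len(np.unique(lv)) != len(lv):
            raise ValueError("delta_c levels must be distinct")
        if np.any(self.n_second < 0) or np.any(self.n_second > self.n_total):
            raise ValueError("need 0 <= n_second <= n_total per level")

    @property
    def proportions(self) -> np.ndarray:
        return self.n_second / self.n_total

    @property
    def n_trials(self) -> int:
        return int(np.sum(self.n_total))


def bin_choices(trials: list[TrialRecord], unit: str) -> BinnedChoices:
    """Tally "second" answers per distinct contrast difference.

    ``unit`` selects whose answer is tallied: an individual member
    ("member_0" / "member_1") or the dyad ("dyad": the common choice on
    agreement trials, the group choice otherwise).
    """
    if not trials:
        raise ValueError("no trials to bin")
    counts: dict[float, list[int]] = {}
    for rec in trials:
        if unit == "member_0":
            resp = rec.choice_0
        elif unit == "member_1":
            resp = rec.choice_1
        elif unit == "dyad":
            resp = rec.final_choice  # raises on missing group choice
        else:
            raise ValueError(f"unknown unit {unit!r}")
        c = counts.setdefault(rec.condition.delta_c, [0, 0])
        c[0] += resp == SECOND
        c[1] += 1
    levels = np.array(sorted(counts))
    return BinnedChoices(
        delta_c_levels=levels,
        n_second=np.array([counts[lv][0] for lv in levels]),
        n_total=np.array([counts[lv][1] for lv in levels]),
    )


def _probit_init(binned: BinnedChoices) -> tuple[float, float]:
    """Starting point from a probit-transformed linear regression."""
    p = np.clip(binned.proportions, 1e-3, 1 - 1e-3)
    z = special.ndtri(p)
    slope, intercept = np.polyfit(binned.delta_c_levels, z, 1)
    if slope <= 0:
        return 0.0, 10.0
    sigma0 = float(np.clip(1.0 / slope, *SIGMA_BOUNDS))
    b0 = float(np.clip(intercept * sigma0, *BIAS_BOUNDS))
    return b0, sigma0


def fit_psychometric(binned: BinnedChoices, method: str = "least_squares") -> PsychometricFit:
    """Fit (b, sigma) to binned choice proportions.

    ``least_squares`` (default) minimises the unweighted squared error
    between per-level proportions and the cumulative Gaussian, the classic
    curve-fitting approach; ``binomial_mle`` maximises the binomial
    likelihood instead and is the statistically preferred option. sigma is
    searched within [0.1, 100] contrast-percent.
    """
    if len(binned.delta_c_levels) < 2:
        raise ValueError("need at least two distinct contrast levels")
    total_second = int(np.sum(binned.n_second))
    if total_second == 0 or total_second == binned.n_trials:
        raise ValueError("non-identifiable: all responses identical")

    x = binned.delta_c_levels
    b0, s0 = _probit_init(binned)
    lo = (BIAS_BOUNDS[0], SIGMA_BOUNDS[0])
    hi = (BIAS_BOUNDS[1], SIGMA_BOUNDS[1])

    if method == "least_squares":
        p_obs = binned.proportions

        def resid(theta: np.ndarray) -> np.ndarray:
            return psychometric(x, theta[0], theta[1]) - p_obs

        sol = optimize.least_squares(resid, x0=[b0, s0], bounds=(lo, hi))
        bias, sigma = sol.x
        converged = bool(sol.success)
    elif method == "binomial_mle":
        k, n = binned.n_second, binned.n_total

        def nll(theta: np.ndarray) -> float:
            p = np.clip(psychometric(x, theta[0], theta[1]), 1e-12, 1 - 1e-12)
            return -float(np.sum(special.xlogy(k, p) + special.xlogy(n - k, 1 - p)))

        sol = optimize.minimize(
            nll, x0=[b0, s0], method="L-BFGS-B", bounds=list(zip(lo, hi))
        )
        bias, sigma = sol.x
        converged = bool(sol.success)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    return PsychometricFit(
        bias_b=float(bias),
        sigma=float(sigma),
        n_trials=binned.n_trials,
        fit_method=method,
        converged=converged,
    )
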