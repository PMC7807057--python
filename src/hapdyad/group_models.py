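"""Group-decision models: closed-form dyad psychometric predictions.

Under Weighted Confidence Sharing (WCS) the two members share their
normalised decision variables z/sigma and the dyad decides by their sum.
That yields closed-form dyad parameters from the members' individual fits:

    b_dyad     = (sigma_2 * b_1 + sigma_1 * b_2) / (sigma_1 + sigma_2)
    sigma_dyad = sqrt(2) * sigma_1 * sigma_2 / (sigma_1 + sigma_2)
    s_dyad     = (s_1 + s_2) / sqrt(2)

so the dyad beats its best member exactly when the member sensitivity ratio
s_min/s_max exceeds sqrt(2) - 1 (~0.4). The alternative rules compared
against WCS are Coin Flip (CF, conflicts resolved at random), Behaviour and
Feedback (BF, defer to the historically better member) and Direct Signal
Sharing (DSS, optimal variance-weighted combination of the raw signals);
their closed forms follow the source that introduced them and each
prediction is flagged accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .psychometrics import PsychometricFit, sigma_from_slope, slope_from_sigma

__all__ = [
    "DyadPrediction",
    "WeightedWCSParams",
    "DyadSummary",
    "wcs_predict",
    "critical_ratio",
    "improvement_line",
    "alternative_predict",
    "classify_dyads",
    "SIMILARITY_THRESHOLD",
]

SQRT2 = math.sqrt(2.0)

#: Dyads with member slope ratio above this are classed "similar" (the exact
#: WCS break-even point sqrt(2)-1 rounds to it at one decimal).
SIMILARITY_THRESHOLD = 0.4


@dataclass(frozen=True)
class DyadPrediction:
    """Model-predicted dyad psychometric parameters."""

    model: str  # WCS | WCS_weighted | CF | BF | DSS
    b_dyad: float
    sigma_dyad: float
    s_dyad: float
    formula_source: str = "stated"  # "cited-source" for CF/BF/DSS

    def __post_init__(self) -> None:
        if abs(self.s_dyad - slope_from_sigma(self.sigma_dyad)) > 1e-9 * max(
            1.0, self.s_dyad
        ):
            raise ValueError("s_dyad inconsistent with sigma_dyad")


@dataclass(frozen=True)
class WeightedWCSParams:
    """Relative decision weights alpha (less-sensitive member) and beta
    (more-sensitive member); over-weighting the best member means
    beta > alpha > 0, i.e. gamma = alpha/beta < 1."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.beta > self.alpha > 0):
            raise ValueError("weights must satisfy beta > alpha > 0")

    @property
    def gamma(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class DyadSummary:
    """One dyad's member slopes and observed joint slope."""

    dyad_id: int
    s_min: float
    s_max: float
    s_dyad_observed: float

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max):
            raise ValueError("need 0 < s_min <= s_max")

    @property
    def ratio(self) -> float:
        return self.s_min / self.s_max

    @property
    def improvement(self) -> float:
        return self.s_dyad_observed / self.s_max

    @property
    def similarity_class(self) -> str:
        return "similar" if self.ratio >= SIMILARITY_THRESHOLD else "different"


def wcs_predict(fit_1: PsychometricFit, fit_2: PsychometricFit) -> DyadPrediction:
    """Closed-form WCS dyad prediction from the two member fits.

    Symmetric under member swap.
    """
    s1, s2 = fit_1.sigma, fit_2.sigma
    if s1 <= 0 or s2 <= 0:
        raise ValueError("member sigmas must be positive")
    b_dyad = (s2 * fit_1.bias_b + s1 * fit_2.bias_b) / (s1 + s2)
    sigma_dyad = SQRT2 * s1 * s2 / (s1 + s2)
    return DyadPrediction(
        model="WCS",
        b_dyad=b_dyad,
        sigma_dyad=sigma_dyad,
        s_dyad=slope_from_sigma(sigma_dyad),
    )


def critical_ratio() -> float:
    """Member slope ratio at which the WCS dyad exactly matches its best
    member: 2/sqrt(2) - 1 = sqrt(2) - 1, which rounds to 0.4."""
    return SQRT2 - 1.0


def improvement_line(ratio: float, weights: WeightedWCSParams | None = None) -> float:
    """Predicted dyad improvement s_dyad/s_max as a function of the member
    ratio s_min/s_max.

    Unweighted WCS gives the line sqrt(2)/2 + (sqrt(2)/2) * ratio (slope and
    intercept both ~0.71). With over-weighting of the best member the slope
    shrinks by gamma = alpha/beta < 1 while the intercept is unchanged.
    """
    if not (0 < ratio <= 1):
        raise ValueError("ratio must lie in (0, 1]")
    gamma = 1.0 if weights is None else weights.gamma
    return SQRT2 / 2.0 + (SQRT2 / 2.0) * gamma * ratio


def alternative_predict(
    fit_1: PsychometricFit, fit_2: PsychometricFit, model: str
) -> DyadPrediction:
    """CF / BF / DSS dyad predictions (closed forms from the cited source).

    BF inherits the better member's parameters; DSS combines signals with
    inverse-variance weights, giving s_dyad = sqrt(s1^2 + s2^2); CF averages
    the member slopes.
    """
    if fit_1.sigma <= 0 or fit_2.sigma <= 0:
        raise ValueError("member sigmas must be positive")
    s1, s2 = fit_1.slope_s, fit_2.slope_s
    if model == "BF":
        best = fit_1 if s1 >= s2 else fit_2
        s_dyad, b_dyad = best.slope_s, best.bias_b
    elif model == "DSS":
        s_dyad = math.hypot(s1, s2)
        w1, w2 = 1.0 / fit_1.sigma**2, 1.0 / fit_2.sigma**2
        b_dyad = (w1 * fit_1.bias_b + w2 * fit_2.bias_b) / (w1 + w2)
    elif model == "CF":
        s_dyad = 0.5 * (s1 + s2)
        b_dyad = 0.5 * (fit_1.bias_b + fit_2.bias_b)
    else:
        raise ValueError(f"unknown alternative model {model!r}")
    return DyadPrediction(
        model=model,
        b_dyad=b_dyad,
        sigma_dyad=sigma_from_slope(s_dyad),
        s_dyad=s_dyad,
        formula_source="cited-source",
    )


def classify_dyads(summaries: list[DyadSummary]) -> dict[str, list[DyadSummary]]:
    """Partition dyads into similar- and different-sensitivity classes at
    the 0.4 ratio threshold (ties classed similar)."""
    out: dict[str, list[DyadSummary]] = {"similar": [], "different": []}
    for s in summaries:
        out[s.similarity_class].append(s)
    return out
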