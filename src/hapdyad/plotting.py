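"""Basic diagnostic figures (psychometric curves and the improvement line).

matplotlib is imported lazily so the analysis path has no plotting
dependency.
"""

from __future__ import annotations

import numpy as np

from .group_models import SQRT2, DyadSummary
from .psychometrics import BinnedChoices, PsychometricFit


def plot_psychometric(binned: BinnedChoices, fit: PsychometricFit, ax=None):
    """Per-level proportions with the fitted cumulative Gaussian overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(binned.delta_c_levels, binned.proportions, "o", label="data")
    grid = np.linspace(binned.delta_c_levels.min(), binned.delta_c_levels.max(), 200)
    ax.plot(grid, fit.predict(grid), "-", label=f"fit (b={fit.bias_b:.2f}, σ={fit.sigma:.2f})")
    ax.set_xlabel("contrast difference ΔC (%)")
    ax.set_ylabel('P(answer "second")')
    ax.legend()
    return ax


def plot_improvement(summaries: list[DyadSummary], ax=None):
    """Dyad improvement vs member ratio with the theoretical WCS line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    r = np.array([s.ratio for s in summaries])
    y = np.array([s.improvement for s in summaries])
    ax.plot(r, y, "o", label="dyads")
    grid = np.linspace(0.0, 1.0, 50)
    ax.plot(grid, SQRT2 / 2 * (1 + grid), "r-", label="WCS prediction")
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.axvline(SQRT2 - 1, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("member ratio s_min / s_max")
    ax.set_ylabel("improvement s_dyad / s_max")
    ax.legend()
    return ax
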