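"""Cohort-level statistics and pipeline orchestration.

Given a cohort of dyads (simulated here, or imported logs), this module
reproduces the group-level analyses: does each similarity class of dyads
out- or under-perform its best member, do observed dyad slopes match the
WCS closed form, and how does dyad improvement scale with the member
sensitivity ratio (ordinary least squares, plus the over-weighting
coefficient gamma estimated with the intercept pinned at sqrt(2)/2).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import io as hio
from .group_models import (
    SQRT2,
    DyadPrediction,
    DyadSummary,
    classify_dyads,
    wcs_predict,
)
from .haptic_features import TABLE_THRESHOLDS, predictor_accuracy, velocity_ratios
from .psychometrics import PsychometricFit, bin_choices, fit_psychometric
from .sim_experiment import ObserverParams, SimConfig, run_experiment

__all__ = [
    "CohortConfig",
    "DyadResult",
    "TTestResult",
    "RegressionResult",
    "CohortResult",
    "compare_dyad_vs_best",
    "observed_vs_wcs",
    "improvement_regression",
    "run_pipeline",
]


@dataclass(frozen=True)
class CohortConfig:
    """A cohort of simulated dyads.

    Member noise levels sigma are drawn log-uniformly from ``sigma_range``
    (contrast-percent) and biases from Normal(0, ``bias_sd``), giving a
    spread of member sensitivity ratios on both sides of the 0.4 boundary.
    """

    n_dyads: int = 19
    n_blocks: int = 8
    sigma_range: tuple[float, float] = (3.0, 15.0)
    bias_sd: float = 1.5
    group_model: str = "WCS"
    fit_method: str = "least_squares"
    dyad_fit_disagreement_only: bool = False
    simulate_trajectories: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("cohort must contain at least one dyad")
        lo, hi = self.sigma_range
        if not (0 < lo <= hi):
            raise ValueError("bad sigma_range")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    p_value: float
    n: int
    mean_diff: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    f_statistic: float
    df_resid: int
    p_value: float
    n: int
    gamma_hat: float


@dataclass(frozen=True)
class DyadResult:
    """Everything computed for one dyad."""

    dyad_id: int
    fit_0: PsychometricFit
    fit_1: PsychometricFit
    fit_dyad: PsychometricFit
    wcs: DyadPrediction
    summary: DyadSummary


@dataclass(frozen=True)
class CohortResult:
    dyads: list[DyadResult]
    similar_vs_best: TTestResult | None
    different_vs_best: TTestResult | None
    observed_vs_wcs_slope: TTestResult | None
    regression: RegressionResult | None
    predictor_reports: dict[str, object] = field(default_factory=dict)
    velocity_means: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if x is None:
                return None
            if hasattr(x, "to_dict"):
                return x.to_dict()
            if hasattr(x, "__dataclass_fields__"):
                return {k: conv(v) for k, v in asdict(x).items()}
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return {
            "dyads": [conv(d) for d in self.dyads],
            "similar_vs_best": conv(self.similar_vs_best),
            "different_vs_best": conv(self.different_vs_best),
            "observed_vs_wcs_slope": conv(self.observed_vs_wcs_slope),
            "regression": conv(self.regression),
            "predictor_reports": conv(self.predictor_reports),
            "velocity_means": conv(self.velocity_means),
        }


def _one_sample(diffs: np.ndarray) -> TTestResult:
    if np.all(diffs == 0.0):  # degenerate: no effect, no variance
        return TTestResult(0.0, len(diffs) - 1, 1.0, len(diffs), 0.0)
    res = stats.ttest_1samp(diffs, 0.0)
    return TTestResult(
        statistic=float(res.statistic),
        df=len(diffs) - 1,
        p_value=float(res.pvalue),
        n=len(diffs),
        mean_diff=float(np.mean(diffs)),
    )


def compare_dyad_vs_best(
    summaries: list[DyadSummary], similarity_class: str
) -> TTestResult:
    """Paired comparison of dyad slope vs best-member slope within one
    similarity class: a one-sample t-test on s_dyad - s_max, df = n - 1."""
    cls = [s for s in summaries if s.similarity_class == similarity_class]
    if len(cls) < 2:
        raise ValueError(f"class {similarity_class!r} has fewer than 2 dyads")
    return _one_sample(np.array([s.s_dyad_observed - s.s_max for s in cls]))


def observed_vs_wcs(dyads: list[DyadResult]) -> TTestResult:
    """One-sample t-test of observed dyad slope minus its WCS prediction."""
    if len(dyads) < 2:
        raise ValueError("need at least 2 dyads")
    return _one_sample(
        np.array([d.fit_dyad.slope_s - d.wcs.s_dyad for d in dyads])
    )


def improvement_regression(summaries: list[DyadSummary]) -> RegressionResult:
    """OLS of dyad improvement s_dyad/s_max on member ratio s_min/s_max,
    plus the over-weighting coefficient gamma estimated by least squares
    with the intercept fixed at sqrt(2)/2."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 dyads for the regression")
    r = np.array([s.ratio for s in summaries])
    y = np.array([s.improvement for s in summaries])
    if np.ptp(r) == 0:
        raise ValueError("degenerate design: all member ratios identical")
    model = sm.OLS(y, sm.add_constant(r)).fit()
    half_sqrt2 = SQRT2 / 2.0
    gamma_hat = float(np.sum(r * (y - half_sqrt2)) / (half_sqrt2 * np.sum(r * r)))
    return RegressionResult(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df_resid=int(model.df_resid),
        p_value=float(model.f_pvalue),
        n=len(summaries),
        gamma_hat=gamma_hat,
    )


def _observer_cohort(cfg: CohortConfig) -> list[tuple[ObserverParams, ObserverParams]]:
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.sigma_range
    pairs = []
    for _ in range(cfg.n_dyads):
        sigmas = np.exp(rng.uniform(math.log(lo), math.log(hi), size=2))
        biases = rng.normal(0.0, cfg.bias_sd, size=2)
        pairs.append(
            (
                ObserverParams(bias_b=float(biases[0]), sigma=float(sigmas[0])),
                ObserverParams(bias_b=float(biases[1]), sigma=float(sigmas[1])),
            )
        )
    return pairs


def run_pipeline(cfg: CohortConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Simulate a cohort, fit all psychometric functions, and compute every
    group-level statistic and haptic predictor report.

    Deterministic given ``cfg.seed``; when ``out_dir`` is given, writes
    trials.csv, trajectories.csv, fits.json, report.json and summary.txt.
    """
    observers = _observer_cohort(cfg)
    seed_rng = np.random.default_rng(cfg.seed + 1)
    all_trials, all_trajs, dyads = [], [], []
    for d, obs_pair in enumerate(observers):
        sim = SimConfig(
            n_blocks=cfg.n_blocks,
            observers=obs_pair,
            group_model=cfg.group_model,
            simulate_trajectories=cfg.simulate_trajectories,
            dyad_id=d,
            seed=int(seed_rng.integers(0, 2**31 - 1)),
        )
        records, trajs = run_experiment(sim)
        all_trials.extend(records)
        all_trajs.extend(trajs)

        fit0 = fit_psychometric(bin_choices(records, "member_0"), cfg.fit_method)
        fit1 = fit_psychometric(bin_choices(records, "member_1"), cfg.fit_method)
        dyad_trials = (
            [r for r in records if not r.agreed]
            if cfg.dyad_fit_disagreement_only
            else records
        )
        fitd = fit_psychometric(bin_choices(dyad_trials, "dyad"), cfg.fit_method)
        pred = wcs_predict(fit0, fit1)
        s_lo, s_hi = sorted((fit0.slope_s, fit1.slope_s))
        dyads.append(
            DyadResult(
                dyad_id=d,
                fit_0=fit0,
                fit_1=fit1,
                fit_dyad=fitd,
                wcs=pred,
                summary=DyadSummary(
                    dyad_id=d, s_min=s_lo, s_max=s_hi, s_dyad_observed=fitd.slope_s
                ),
            )
        )

    summaries = [d.summary for d in dyads]
    classes = classify_dyads(summaries)

    def safe_ttest(cls: str) -> TTestResult | None:
        try:
            return compare_dyad_vs_best(summaries, cls)
        except ValueError:
            return None

    result = CohortResult(
        dyads=dyads,
        similar_vs_best=safe_ttest("similar"),
        different_vs_best=safe_ttest("different"),
        observed_vs_wcs_slope=observed_vs_wcs(dyads) if len(dyads) >= 2 else None,
        regression=improvement_regression(summaries) if len(summaries) >= 3 else None,
    )

    predictor_reports: dict[str, object] = {}
    velocity_means: dict[str, float] = {}
    if all_trajs:
        for pred_name in ("first_mover_rt", "1C", "peak_force", "work"):
            predictor_reports[pred_name] = predictor_accuracy(
                all_trials, all_trajs, pred_name, TABLE_THRESHOLDS
            )
        vel = velocity_ratios(all_trials, all_trajs)
        if len(vel):
            velocity_means = {
                "ratio_l_mean": float(vel["ratio_l"].mean()),
                "ratio_f_mean": float(vel["ratio_f"].mean()),
                "n_trials": int(len(vel)),
            }
    result = CohortResult(
        dyads=result.dyads,
        similar_vs_best=result.similar_vs_best,
        different_vs_best=result.different_vs_best,
        observed_vs_wcs_slope=result.observed_vs_wcs_slope,
        regression=result.regression,
        predictor_reports=predictor_reports,
        velocity_means=velocity_means,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_trials(all_trials, out / "trials.csv")
        hio.write_trajectories(all_trajs, out / "trajectories.csv")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        (out / "summary.txt").write_text(summarise(result, classes), encoding="utf-8")
    return result


def summarise(result: CohortResult, classes: dict | None = None) -> str:
    """Human-readable cohort summary."""
    if classes is None:
        classes = classify_dyads([d.summary for d in result.dyads])
    lines = [
        f"dyads: {len(result.dyads)} "
        f"(similar: {len(classes['similar'])}, different: {len(classes['different'])})",
    ]
    for name, t in (
        ("similar vs best", result.similar_vs_best),
        ("different vs best", result.different_vs_best),
        ("observed vs WCS slope", result.observed_vs_wcs_slope),
    ):
        if t is None:
            lines.append(f"{name}: not computed (class too small)")
        else:
            lines.append(
                f"{name}: mean diff {t.mean_diff:+.4f}, t({t.df}) = {t.statistic:.2f},"
                f" p = {t.p_value:.4g}, n = {t.n}"
            )
    if result.regression is not None:
        reg = result.regression
        lines.append(
            f"improvement ~ ratio: slope {reg.slope:.3f} ± {reg.slope_se:.3f}, "
            f"intercept {reg.intercept:.3f} ± {reg.intercept_se:.3f}, "
            f"R² = {reg.r_squared:.3f}, F(1,{reg.df_resid}) = {reg.f_statistic:.2f}, "
            f"p = {reg.p_value:.4g}, n = {reg.n}; gamma = {reg.gamma_hat:.3f}"
        )
    for name, rep in result.predictor_reports.items():
        acc = getattr(rep, "accuracy", float("nan"))
        lines.append(f"predictor {name}: accuracy {acc:.3f} (n = {rep.n_trials})")
        sweep = getattr(rep, "per_threshold", None)
        if sweep:
            lines.append(
                "  1C sweep: "
                + ", ".join(f"{thr:.2f}: {a:.3f}" for thr, a in sweep.items())
            )
    if result.velocity_means:
        vm = result.velocity_means
        lines.append(
            f"velocity ratios: VeloL/VeloD {vm['ratio_l_mean']:.4f}, "
            f"VeloF/VeloD {vm['ratio_f_mean']:.4f} (n = {vm['n_trials']})"
        )
    return "\n".join(lines) + "\n"
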