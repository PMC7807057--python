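"""Leadership features of group-phase handle trajectories.

On a disagreement trial the Leader is the member whose individual choice
equals the final group choice. This module extracts the kinematic and
kinetic signatures of leadership from the coupled-handle recordings — the
first threshold crossing (1C), peak applied force, per-sample-normalised
mechanical work, and leader/follower/dyad mean velocities — and scores each
as a predictor of the group choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim_experiment import FIRST, SECOND, Trajectory, TrialRecord

__all__ = [
    "CrossingEvent",
    "PredictorReport",
    "TABLE_THRESHOLDS",
    "first_crossing",
    "mechanical_work",
    "peak_force",
    "label_leader",
    "predictor_accuracy",
    "velocity_ratios",
]

#: Threshold sweep used when scoring the first-crossing predictor.
TABLE_THRESHOLDS = (0.05, 0.08, 0.10, 0.15, 0.20, 0.25, 0.30)

LEFT, RIGHT = "left", "right"
_SIDE_TO_CHOICE = {LEFT: FIRST, RIGHT: SECOND}


@dataclass(frozen=True)
class CrossingEvent:
    """First exit of either handle from the symmetric start zone
    [-threshold, +threshold]."""

    side: str  # left | right
    member: int  # 0 | 1
    sample_index: int
    threshold: float

    @property
    def implied_choice(self) -> str:
        return _SIDE_TO_CHOICE[self.side]


def first_crossing(traj: Trajectory, threshold: float) -> CrossingEvent | None:
    """Earliest sample at which either member's handle leaves the zone
    +/-threshold around the start; ``None`` if neither ever does.

    A simultaneous exit by both members is attributed to the handle with the
    larger displacement, then to the lower member index.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    x0, x1 = np.abs(traj.x_0), np.abs(traj.x_1)
    if max(x0[0], x1[0]) > 1.0:
        raise ValueError("positions are not normalised to [-1, 1]")
    out = (x0 > threshold) | (x1 > threshold)
    hits = np.flatnonzero(out)
    if hits.size == 0:
        return None
    k = int(hits[0])
    crossed = [i for i in (0, 1) if (x0, x1)[i][k] > threshold]
    if len(crossed) == 2:  # tie: larger excursion wins, then member 0
        member = 0 if x0[k] >= x1[k] else 1
    else:
        member = crossed[0]
    side = RIGHT if traj.position(member)[k] > 0 else LEFT
    return CrossingEvent(side=side, member=member, sample_index=k, threshold=threshold)


def mechanical_work(traj: Trajectory, member: int) -> float:
    """Per-sample-normalised mechanical work of one member:

        W_i = (1/N) * sum_k F_i[k] * (X_i[k] - X_i[k-1])

    with N the number of summed increments. Negative values mean the member
    resisted the ongoing motion of its own handle.
    """
    x = traj.position(member)
    f = traj.force(member)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    dx = np.diff(x)
    return float(np.sum(f[1:] * dx) / len(dx))


def peak_force(traj: Trajectory, member: int) -> float:
    """Largest force magnitude the member applied, in newtons."""
    return float(np.max(np.abs(traj.force(member))))


def label_leader(trial: TrialRecord) -> int:
    """The member whose individual choice equals the group choice."""
    if trial.agreed:
        raise ValueError("leadership is only defined on disagreement trials")
    return 0 if trial.choice_0 == trial.final_choice else 1


@dataclass(frozen=True)
class PredictorReport:
    """Accuracy of one group-choice predictor over a trial set."""

    predictor: str
    n_trials: int
    accuracy: float
    per_threshold: dict[float, float] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


def _paired(
    trials: list[TrialRecord], trajectories: list[Trajectory]
) -> tuple[list[tuple[TrialRecord, Trajectory]], int]:
    """Align disagreement trials with their trajectories by trial index."""
    by_idx = {(t.dyad_id, t.trial_index): t for t in trajectories}
    pairs, skipped = [], 0
    for rec in trials:
        if rec.agreed:
            continue
        traj = by_idx.get((rec.dyad_id, rec.condition.trial_index))
        if traj is None:
            skipped += 1
        else:
            pairs.append((rec, traj))
    return pairs, skipped


def predictor_accuracy(
    trials: list[TrialRecord],
    trajectories: list[Trajectory],
    predictor: str,
    thresholds: tuple[float, ...] = TABLE_THRESHOLDS,
    reference_threshold: float = 0.05,
) -> PredictorReport:
    """Score one predictor of the group choice on disagreement trials.

    ``first_mover_rt`` predicts the faster individual responder leads;
    ``1C`` predicts the choice on the side of the first threshold crossing
    (accuracy reported per threshold in the sweep, headline accuracy at
    ``reference_threshold``); ``peak_force`` and ``work`` predict that the
    member applying the larger value leads. Disagreement trials with no
    matching trajectory are skipped and counted.
    """
    pairs, skipped = _paired(trials, trajectories)
    if predictor == "first_mover_rt":
        rows = [
            ((0 if rec.rt_0 <= rec.rt_1 else 1) == label_leader(rec))
            for rec, _ in pairs
        ]
        return PredictorReport(
            predictor=predictor,
            n_trials=len(rows),
            accuracy=float(np.mean(rows)) if rows else 0.0,
            n_skipped=skipped,
        )
    if predictor == "1C":
        sweep: dict[float, float] = {}
        n_used = 0
        for thr in thresholds:
            hits, n = 0, 0
            for rec, traj in pairs:
                ev = first_crossing(traj, thr)
                if ev is None:
                    continue
                n += 1
                hits += ev.implied_choice == rec.final_choice
            sweep[thr] = hits / n if n else math.nan
            if thr == reference_threshold:
                n_used = n
        acc = sweep.get(reference_threshold, math.nan)
        return PredictorReport(
            predictor=predictor,
            n_trials=n_used,
            accuracy=float(acc),
            per_threshold=sweep,
            n_skipped=skipped,
        )
    if predictor in ("peak_force", "work"):
        feat = mechanical_work if predictor == "work" else peak_force
        rows = [
            ((0 if feat(traj, 0) >= feat(traj, 1) else 1) == label_leader(rec))
            for rec, traj in pairs
        ]
        return PredictorReport(
            predictor=predictor,
            n_trials=len(rows),
            accuracy=float(np.mean(rows)) if rows else 0.0,
            n_skipped=skipped,
        )
    raise ValueError(f"unknown predictor {predictor!r}")


def velocity_ratios(
    trials: list[TrialRecord],
    trajectories: list[Trajectory],
    reference_threshold: float = 0.05,
    use_individual_handles: bool = True,
) -> pd.DataFrame:
    """Per-trial leader/follower/dyad velocity ratios.

    The trajectory is split at the first crossing of ``reference_threshold``.
    Segment 1 (before the crossing) gives the leader's and follower's mean
    handle speeds VeloL and VeloF; segment 2 (after it) gives the combined
    cursor's mean speed VeloD. With ``use_individual_handles`` off, VeloL and
    VeloF are instead read from the combined cursor, grouped by leader
    identity — meaningful only as a robustness check since the two coincide
    under rigid coupling. Trials with an empty segment or zero dyad speed
    are excluded.

    Returns a frame with columns ``dyad_id, trial_index, leader,
    velo_l, velo_f, velo_d, ratio_l, ratio_f``.
    """
    pairs, _ = _paired(trials, trajectories)
    rows = []
    for rec, traj in pairs:
        ev = first_crossing(traj, reference_threshold)
        if ev is None:
            continue
        k = ev.sample_index
        if k < 2 or k >= len(traj.sample_times) - 1:
            continue
        dt = traj.dt
        leader = label_leader(rec)
        if use_individual_handles:
            seg1_l = traj.position(leader)[: k + 1]
            seg1_f = traj.position(1 - leader)[: k + 1]
        else:
            seg1_l = seg1_f = traj.combined[: k + 1]
        velo_l = float(np.mean(np.abs(np.diff(seg1_l)))) / dt
        velo_f = float(np.mean(np.abs(np.diff(seg1_f)))) / dt
        velo_d = float(np.mean(np.abs(np.diff(traj.combined[k:])))) / dt
        if velo_d == 0.0:
            continue
        rows.append(
            {
                "dyad_id": rec.dyad_id,
                "trial_index": rec.condition.trial_index,
                "leader": leader,
                "velo_l": velo_l,
                "velo_f": velo_f,
                "velo_d": velo_d,
                "ratio_l": velo_l / velo_d,
                "ratio_f": velo_f / velo_d,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dyad_id",
            "trial_index",
            "leader",
            "velo_l",
            "velo_f",
            "velo_d",
            "ratio_l",
            "ratio_f",
        ],
    )
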