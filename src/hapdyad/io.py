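"""Delimited-text serialisation of trial and trajectory logs.

`trials.csv` carries one row per trial; `trajectories.csv` is long-format
(one row per time sample). Both are UTF-8 with '.' decimals so files round-
trip across locales.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sim_experiment import Trajectory, TrialCondition, TrialRecord

__all__ = [
    "trials_to_frame",
    "frame_to_trials",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "write_trials",
    "read_trials",
    "write_trajectories",
    "read_trajectories",
]

TRIAL_COLUMNS = [
    "dyad_id",
    "block",
    "trial",
    "oddball_interval",
    "oddball_contrast",
    "baseline_contrast",
    "delta_c",
    "choice_0",
    "choice_1",
    "confidence_0",
    "confidence_1",
    "rt_0",
    "rt_1",
    "agreed",
    "group_choice",
    "group_correct",
]

TRAJ_COLUMNS = ["dyad_id", "trial_index", "t", "x0", "x1", "f0", "f1"]


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.condition
        rows.append(
            {
                "dyad_id": r.dyad_id,
                "block": c.block_index,
                "trial": c.trial_index,
                "oddball_interval": c.oddball_interval,
                "oddball_contrast": c.oddball_contrast,
                "baseline_contrast": c.baseline_contrast,
                "delta_c": c.delta_c,
                "choice_0": r.choice_0,
                "choice_1": r.choice_1,
                "confidence_0": r.confidence_0,
                "confidence_1": r.confidence_1,
                "rt_0": r.rt_0,
                "rt_1": r.rt_1,
                "agreed": r.agreed,
                "group_choice": r.group_choice if r.group_choice is not None else "",
                "group_correct": r.group_correct,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            cond = TrialCondition(
                block_index=int(row.block),
                trial_index=int(row.trial),
                oddball_interval=str(row.oddball_interval),
                oddball_contrast=float(row.oddball_contrast),
                baseline_contrast=float(row.baseline_contrast),
            )
            gc = row.group_choice
            group_choice = None if (pd.isna(gc) or gc == "") else str(gc)
            conf0 = None if pd.isna(row.confidence_0) else float(row.confidence_0)
            conf1 = None if pd.isna(row.confidence_1) else float(row.confidence_1)
            records.append(
                TrialRecord(
                    dyad_id=int(row.dyad_id),
                    condition=cond,
                    choice_0=str(row.choice_0),
                    choice_1=str(row.choice_1),
                    confidence_0=conf0,
                    confidence_1=conf1,
                    rt_0=float(row.rt_0),
                    rt_1=float(row.rt_1),
                    group_choice=group_choice,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"trials row {i}: {exc}") from exc
    return records


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    parts = []
    for tr in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "dyad_id": tr.dyad_id,
                    "trial_index": tr.trial_index,
                    "t": tr.sample_times,
                    "x0": tr.x_0,
                    "x1": tr.x_1,
                    "f0": tr.f_0,
                    "f1": tr.f_1,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRAJ_COLUMNS)
    return pd.concat(parts, ignore_index=True)[TRAJ_COLUMNS]


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for (dyad_id, trial_index), g in df.groupby(["dyad_id", "trial_index"], sort=True):
        g = g.sort_values("t")
        out.append(
            Trajectory(
                dyad_id=int(dyad_id),
                trial_index=int(trial_index),
                sample_times=g["t"].to_numpy(dtype=float),
                x_0=g["x0"].to_numpy(dtype=float),
                x_1=g["x1"].to_numpy(dtype=float),
                f_0=g["f0"].to_numpy(dtype=float),
                f_1=g["f1"].to_numpy(dtype=float),
            )
        )
    return out


def write_trials(records: list[TrialRecord], path: str | Path) -> None:
    trials_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def read_trials(path: str | Path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path, keep_default_na=True))


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False, float_format="%.8g")


def read_trajectories(path: str | Path) -> list[Trajectory]:
    return frame_to_trajectories(pd.read_csv(path))
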