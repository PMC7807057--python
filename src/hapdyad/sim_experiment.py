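"""Synthetic dyad-experiment generator.

Emulates a two-interval forced-choice contrast-oddball experiment performed
by pairs of observers (dyads): a balanced block design of oddball timings and
contrast levels, signal-detection observers whose choices follow a cumulative
Gaussian psychometric function, group decisions on disagreement trials under
a selectable combination rule (WCS / CF / BF / DSS), and coupled one-degree-
of-freedom handle trajectories for the group-decision phase in which the
higher-confidence member takes the lead while the other first resists and
then yields.

All randomness is drawn from a single :class:`numpy.random.Generator`
threaded through every function, so a run is fully reproducible from one
integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrialCondition",
    "ObserverParams",
    "TrialRecord",
    "Trajectory",
    "SimConfig",
    "make_schedule",
    "simulate_individual",
    "simulate_group_choice",
    "simulate_trajectory",
    "run_experiment",
]

FIRST = "first"
SECOND = "second"

#: Design defaults: oddball contrast levels and common baseline (fractions).
DEFAULT_LEVELS = (0.115, 0.135, 0.17, 0.25)
DEFAULT_BASELINE = 0.10

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialCondition:
    """Stimulus condition of one two-interval trial.

    ``delta_c`` is the signed contrast difference in percent: contrast of the
    second interval minus the first at the oddball location, so a positive
    value means the correct answer is "second".
    """

    block_index: int
    trial_index: int
    oddball_interval: str  # "first" | "second"
    oddball_contrast: float
    baseline_contrast: float

    def __post_init__(self) -> None:
        if self.oddball_interval not in (FIRST, SECOND):
            raise ValueError(f"bad oddball_interval: {self.oddball_interval!r}")
        if self.oddball_contrast <= self.baseline_contrast:
            raise ValueError("oddball contrast must exceed baseline")

    @property
    def delta_c(self) -> float:
        """Signed contrast difference in percent (second minus first)."""
        d = (self.oddball_contrast - self.baseline_contrast) * 100.0
        return d if self.oddball_interval == SECOND else -d


@dataclass(frozen=True)
class ObserverParams:
    """Signal-detection observer.

    ``bias_b`` and ``sigma`` (contrast-percent units) are the bias and noise
    of the internal decision variable; the remaining fields shape response
    times and motor output of the trajectory generator and have no effect on
    choices.
    """

    bias_b: float = 0.0
    sigma: float = 5.0
    rt_offset: float = 0.30  # seconds
    rt_gain: float = 0.45  # seconds per unit of 1/|confidence|
    motor_noise_sd: float = 0.05  # newtons, per-sample force jitter

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be strictly positive")
        if self.rt_offset < 0 or self.rt_gain < 0 or self.motor_noise_sd < 0:
            raise ValueError("rt/motor parameters must be non-negative")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial: individual choices, and the group resolution
    when the members disagreed."""

    dyad_id: int
    condition: TrialCondition
    choice_0: str
    choice_1: str
    confidence_0: float | None
    confidence_1: float | None
    rt_0: float
    rt_1: float
    group_choice: str | None  # present iff the members disagreed

    @property
    def agreed(self) -> bool:
        return self.choice_0 == self.choice_1

    @property
    def final_choice(self) -> str:
        """Dyad answer: the common choice when agreed, else the group choice."""
        if self.agreed:
            return self.choice_0
        if self.group_choice is None:
            raise ValueError("disagreement trial without a group choice")
        return self.group_choice

    @property
    def group_correct(self) -> bool:
        return self.final_choice == self.condition.oddball_interval

    def __post_init__(self) -> None:
        for c in (self.choice_0, self.choice_1):
            if c not in (FIRST, SECOND):
                raise ValueError(f"bad choice: {c!r}")
        if self.agreed and self.group_choice is not None:
            raise ValueError("group_choice must be absent on agreement trials")


@dataclass(frozen=True)
class Trajectory:
    """Group-phase handle time series for one disagreement trial.

    Positions are normalised so the common start is 0 and the left/right
    response sides are -1 ("first") and +1 ("second"). Forces are the forces
    each member applies to their own handle, in newtons.
    """

    dyad_id: int
    trial_index: int
    sample_times: np.ndarray
    x_0: np.ndarray
    x_1: np.ndarray
    f_0: np.ndarray
    f_1: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_times)
        for name in ("x_0", "x_1", "f_0", "f_1"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != sample_times length")
        if n >= 2:
            dt = np.diff(self.sample_times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("sample_times must be uniform and increasing")
        if np.max(np.abs(self.x_0)) > 1 + 1e-9 or np.max(np.abs(self.x_1)) > 1 + 1e-9:
            raise ValueError("normalised positions must stay within [-1, 1]")

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    def position(self, member: int) -> np.ndarray:
        return (self.x_0, self.x_1)[member]

    def force(self, member: int) -> np.ndarray:
        return (self.f_0, self.f_1)[member]

    @property
    def combined(self) -> np.ndarray:
        """Displayed cursor: mean of the two handle positions."""
        return 0.5 * (self.x_0 + self.x_1)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic dyad experiment.

    Defaults reproduce the experimental design: 8 blocks of 16 trials, four
    oddball contrast levels (11.5, 13.5, 17, 25 %) against a 10 % baseline.
    """

    n_blocks: int = 8
    observers: tuple[ObserverParams, ObserverParams] = (
        ObserverParams(),
        ObserverParams(),
    )
    group_model: str = "WCS"  # WCS | CF | BF | DSS
    baseline_contrast: float = DEFAULT_BASELINE
    oddball_contrast_levels: tuple[float, ...] = DEFAULT_LEVELS
    sample_rate: float = 100.0  # Hz
    coupling_stiffness: float = 4.0  # N per unit of handle separation
    follower_yield_delay: float = 0.45  # s of active resistance before yielding
    simulate_trajectories: bool = True
    dyad_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_model not in GROUP_MODELS:
            raise ValueError(f"unknown group model {self.group_model!r}")
        if self.sample_rate <= 0 or self.coupling_stiffness <= 0:
            raise ValueError("sample_rate and coupling_stiffness must be positive")
        if self.follower_yield_delay < 0:
            raise ValueError("follower_yield_delay must be non-negative")


GROUP_MODELS = ("WCS", "CF", "BF", "DSS")


# ---------------------------------------------------------------------------
# Stimulus schedule
# ---------------------------------------------------------------------------


def make_schedule(
    n_blocks: int,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    baseline: float = DEFAULT_BASELINE,
    seed: int | np.random.Generator = 0,
) -> list[TrialCondition]:
    """Balanced, shuffled stimulus schedule.

    Every (oddball timing x contrast level) combination appears exactly twice
    per block, so a block holds ``2 * 2 * len(levels)`` trials. Trial order
    within each block is shuffled by the seed.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not levels:
        raise ValueError("need at least one contrast level")
    if baseline >= min(levels):
        raise ValueError("baseline contrast must lie below every oddball level")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    combos = [(t, lv) for t in (FIRST, SECOND) for lv in levels] * 2
    schedule: list[TrialCondition] = []
    trial = 0
    for block in range(n_blocks):
        order = rng.permutation(len(combos))
        for idx in order:
            timing, level = combos[idx]
            schedule.append(
                TrialCondition(
                    block_index=block,
                    trial_index=trial,
                    oddball_interval=timing,
                    oddball_contrast=level,
                    baseline_contrast=baseline,
                )
            )
            trial += 1
    return schedule


# ---------------------------------------------------------------------------
# Individual and group decisions
# ---------------------------------------------------------------------------

_RT_JITTER_SD = 0.35  # lognormal sd of the confidence-dependent RT term


def simulate_individual(
    cond: TrialCondition, obs: ObserverParams, rng: np.random.Generator
) -> tuple[str, float, float]:
    """One observer's decision on one trial.

    The internal decision variable is z ~ Normal(delta_c + b, sigma); the
    observer answers "second" iff z > 0, so across many trials the fraction
    of "second" answers converges to the cumulative Gaussian
    H((delta_c + b) / sigma). Confidence is the normalised variable z/sigma,
    and response time falls with confidence:
    rt = rt_offset + (rt_gain / |c|) * lognormal jitter.
    """
    z = rng.normal(cond.delta_c + obs.bias_b, obs.sigma)
    choice = SECOND if z > 0 else FIRST
    conf = z / obs.sigma
    rt = obs.rt_offset + (obs.rt_gain / max(abs(conf), 1e-9)) * rng.lognormal(
        0.0, _RT_JITTER_SD
    )
    return choice, conf, float(min(rt, 30.0))


def simulate_group_choice(
    trial: TrialRecord,
    model: str,
    obs_pair: tuple[ObserverParams, ObserverParams],
    rng: np.random.Generator,
) -> str:
    """Resolve a disagreement trial under a named group-decision rule.

    WCS sums the shared normalised decision variables z/sigma; DSS combines
    the raw variables weighted by 1/sigma^2 (optimal signal sharing); CF
    flips a fair coin; BF defers to the member with the smaller sigma.
    """
    if trial.agreed:
        raise ValueError("group choice is only defined on disagreement trials")
    if trial.confidence_0 is None or trial.confidence_1 is None:
        raise ValueError("simulator confidences required to resolve the conflict")
    c0, c1 = trial.confidence_0, trial.confidence_1
    s0, s1 = obs_pair[0].sigma, obs_pair[1].sigma

    if model == "WCS":
        stat = c0 + c1
    elif model == "DSS":
        # z_i / sigma_i^2 == c_i / sigma_i
        stat = c0 / s0 + c1 / s1
    elif model == "CF":
        return SECOND if rng.random() < 0.5 else FIRST
    elif model == "BF":
        return trial.choice_0 if s0 <= s1 else trial.choice_1
    else:
        raise ValueError(f"unknown group model {model!r}")

    if stat == 0.0:  # measure-zero tie
        return SECOND if rng.random() < 0.5 else FIRST
    return SECOND if stat > 0 else FIRST


# ---------------------------------------------------------------------------
# Coupled-handle trajectory generator
# ---------------------------------------------------------------------------

# Motor-plant constants (not part of the experimental design): an overdamped
# handle driven by each member's applied force plus the coupling spring.
_DAMPING = 2.0  # N*s per unit position
_KP_BASE = 1.5  # N per unit tracking error
_KP_CONF = 0.5  # gain increase per unit |confidence|
_FORCE_CAP = 12.0  # N, per member (the rig displays a ~24 N total budget)
_ONSET_CAP = 2.0  # s
_REACH_DUR_MAX = 1.6  # s, leader reach duration at low confidence
_REACH_DUR_MIN = 0.5  # s
_FOLLOWER_EXCURSION = 0.25  # normalised units toward the follower's own side
_FOLLOWER_REACH = 0.6  # s, follower's push toward its own side
_FOLLOWER_BRAKE = 0.8  # N*s/unit: viscous resistance while being dragged
_VALIDATION_ZONE = 0.9  # |combined| needed to validate an answer
_HOLD_TIME = 1.0  # s the combined cursor must remain in the zone
_MAX_DURATION = 20.0  # s, hard simulation cap


def _min_jerk(t: np.ndarray, duration: float) -> np.ndarray:
    """Minimum-jerk position profile from 0 to 1 over `duration` seconds."""
    s = np.clip(t / duration, 0.0, 1.0)
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


def _onset_time(obs: ObserverParams, conf: float, rng: np.random.Generator) -> float:
    """Movement onset: confident members start earlier (rt law, jittered)."""
    base = obs.rt_gain / max(abs(conf), 1e-9)
    return min(obs.rt_offset + base * rng.lognormal(0.0, _RT_JITTER_SD), _ONSET_CAP)


def simulate_trajectory(
    trial: TrialRecord, cfg: SimConfig, rng: np.random.Generator
) -> Trajectory:
    """Coupled group-phase trajectory for one disagreement trial.

    The member whose individual choice matches the group choice (the Leader)
    drives a minimum-jerk reach to the winning side, starting earlier and
    pushing harder the more confident it is. The other member (the Follower)
    first pushes toward its own side for ``follower_yield_delay`` seconds
    after its own onset, then yields: it stops driving and is dragged through
    the coupling spring while applying a small viscous braking force against
    the motion, so its net mechanical work is non-positive in expectation.
    The trial ends once the combined cursor has stayed in the validation zone
    for one second.
    """
    if trial.agreed:
        raise ValueError("trajectories exist only for disagreement trials")
    group = trial.final_choice
    target = 1.0 if group == SECOND else -1.0
    leader = 0 if trial.choice_0 == group else 1
    follower = 1 - leader

    obs = cfg.observers
    confs = (trial.confidence_0 or 0.0, trial.confidence_1 or 0.0)
    onset = [_onset_time(obs[i], confs[i], rng) for i in (0, 1)]
    c_lead = abs(confs[leader])

    reach_dur = float(
        np.clip(_REACH_DUR_MAX / (1.0 + 0.25 * c_lead), _REACH_DUR_MIN, _REACH_DUR_MAX)
    )
    yield_time = onset[follower] + cfg.follower_yield_delay
    own_side = _FOLLOWER_EXCURSION * (1.0 if (trial.choice_1 if follower else trial.choice_0) == SECOND else -1.0)
    # position the follower's reference held at the moment it yields
    kp = [
        min(_KP_BASE * (1.0 + _KP_CONF * abs(confs[i])), _FORCE_CAP)
        for i in (0, 1)
    ]

    dt = 1.0 / cfg.sample_rate
    n_max = int(_MAX_DURATION / dt)
    x = np.zeros((2, n_max))
    f = np.zeros((2, n_max))
    k_spring = cfg.coupling_stiffness

    hold_needed = int(round(_HOLD_TIME / dt))
    held = 0
    n_used = n_max
    xi = np.zeros(2)
    vel = np.zeros(2)
    for k_step in range(n_max):
        t = k_step * dt
        # reference positions
        ref = np.zeros(2)
        if t >= onset[leader]:
            ref[leader] = target * _min_jerk(
                np.array([t - onset[leader]]), reach_dur
            )[0]
        active = [False, False]
        active[leader] = t >= onset[leader]
        if t >= onset[follower] and t < yield_time and cfg.follower_yield_delay > 0:
            ref[follower] = own_side * _min_jerk(
                np.array([t - onset[follower]]), _FOLLOWER_REACH
            )[0]
            active[follower] = True
        # applied forces: proportional tracking while active; after yielding
        # the follower brakes gently against whatever motion it is dragged in
        yielded = t >= yield_time
        for i in (0, 1):
            if active[i]:
                u = kp[i] * (ref[i] - xi[i])
            elif i == follower and yielded:
                u = -_FOLLOWER_BRAKE * vel[i]
            else:
                u = 0.0
            u += obs[i].motor_noise_sd * rng.normal()
            f[i, k_step] = float(np.clip(u, -_FORCE_CAP, _FORCE_CAP))
        # overdamped coupled dynamics
        spring = k_spring * (xi[::-1] - xi)
        new_xi = np.clip(xi + dt * (f[:, k_step] + spring) / _DAMPING, -1.0, 1.0)
        vel = (new_xi - xi) / dt
        xi = new_xi
        x[:, k_step] = xi

        if abs(0.5 * (xi[0] + xi[1])) >= _VALIDATION_ZONE:
            held += 1
            if held >= hold_needed:
                n_used = k_step + 1
                break
        else:
            held = 0

    times = np.arange(n_used) * dt
    traj = Trajectory(
        dyad_id=trial.dyad_id,
        trial_index=trial.condition.trial_index,
        sample_times=times,
        x_0=x[0, :n_used].copy(),
        x_1=x[1, :n_used].copy(),
        f_0=f[0, :n_used].copy(),
        f_1=f[1, :n_used].copy(),
    )
    final = traj.combined[-1]
    if math.copysign(1.0, final) != target or abs(final) < _VALIDATION_ZONE:
        raise RuntimeError("trajectory failed to validate on the group-choice side")
    return traj


# ---------------------------------------------------------------------------
# Whole experiment
# ---------------------------------------------------------------------------


def run_experiment(cfg: SimConfig) -> tuple[list[TrialRecord], list[Trajectory]]:
    """Simulate a full experiment for one dyad.

    Returns one :class:`TrialRecord` per scheduled trial and one
    :class:`Trajectory` per disagreement trial (unless
    ``cfg.simulate_trajectories`` is off). Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = make_schedule(
        cfg.n_blocks, cfg.oddball_contrast_levels, cfg.baseline_contrast, rng
    )
    records: list[TrialRecord] = []
    trajectories: list[Trajectory] = []
    for cond in schedule:
        ch0, c0, rt0 = simulate_individual(cond, cfg.observers[0], rng)
        ch1, c1, rt1 = simulate_individual(cond, cfg.observers[1], rng)
        rec = TrialRecord(
            dyad_id=cfg.dyad_id,
            condition=cond,
            choice_0=ch0,
            choice_1=ch1,
            confidence_0=c0,
            confidence_1=c1,
            rt_0=rt0,
            rt_1=rt1,
            group_choice=None,
        )
        if not rec.agreed:
            group = simulate_group_choice(rec, cfg.group_model, cfg.observers, rng)
            rec = replace(rec, group_choice=group)
            if cfg.simulate_trajectories:
                trajectories.append(simulate_trajectory(rec, cfg, rng))
        records.append(rec)
    return records, trajectories
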