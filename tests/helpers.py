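"""Shared fixture builders for the test suite."""

from hapdyad import TrialCondition, TrialRecord
from hapdyad.sim_experiment import FIRST, SECOND


def make_condition(delta, trial_index=0):
    """A trial condition with the requested signed contrast difference (%),
    built on the 10% baseline."""
    level = 0.10 + abs(delta) / 100.0
    return TrialCondition(
        block_index=0,
        trial_index=trial_index,
        oddball_interval=SECOND if delta >= 0 else FIRST,
        oddball_contrast=level,
        baseline_contrast=0.10,
    )


def make_disagreement(c0, c1, delta=3.5, trial_index=0, rt_0=0.5, rt_1=0.7):
    """A disagreement trial record from two signed confidences of opposite
    sign (choices follow the confidence signs; group choice unresolved)."""
    return TrialRecord(
        dyad_id=0,
        condition=make_condition(delta, trial_index),
        choice_0=SECOND if c0 > 0 else FIRST,
        choice_1=SECOND if c1 > 0 else FIRST,
        confidence_0=c0,
        confidence_1=c1,
        rt_0=rt_0,
        rt_1=rt_1,
        group_choice=None,
    )
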