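import numpy as np
import pytest

from tactsim import CohortSpec, default_protocols


@pytest.fixture(scope="session")
def specs():
    return default_protocols()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """A small 8-per-group cohort spec for fast end-to-end tests."""
    from dataclasses import replace
    return replace(CohortSpec(),
                   group_sizes={"TDC": 8, "ASD": 8, "ADHD": 8, "ASD+ADHD": 8})


def replay_staircase(spec, responses):
    """Independent brute-force replay of the tracking rules.

    Returns the sequence of values presented on each tracked trial.
    Deliberately written from scratch (plain loop over the rule text)
    as the oracle for the staircase engine.
    """
    presented = []
    value = spec.start_value
    streak = 0
    for trial_number, correct in enumerate(responses, start=1):
        presented.append(value)
        in_simple_phase = (spec.rule_switch_trial is None
                           or trial_number <= spec.rule_switch_trial)
        move = 0
        if in_simple_phase:
            move = -1 if correct else +1
            streak = 0
        else:
            if correct:
                streak += 1
                if streak == 2:
                    move = -1
                    streak = 0
            else:
                move = +1
                streak = 0
        if move:
            if spec.step_mode == "additive":
                value = value + move * spec.step
            else:
                value = value * (1.0 + move * spec.step)
            value = max(spec.limits[0], min(spec.limits[1], value))
    return presented
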