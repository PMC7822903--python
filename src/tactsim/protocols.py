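"""Adaptive staircase protocols for a vibrotactile 2AFC battery.

Four protocols are modelled, each tracking one stimulus variable with a
transformed up/down staircase delivered to digits 2 and 3 of one hand:

* ``detection`` — amplitude (μm) of a single 25 Hz pulse; start 20 μm,
  24 trials, one-up–one-down for the first ten trials then a two-correct
  rule for the remainder.
* ``amplitude_discrimination`` — amplitude difference (μm) between a
  100 μm standard and a comparison stimulus; start 100 μm, ±10 μm steps,
  20 trials, rule switch after trial 10.
* ``frequency_discrimination`` — frequency difference (Hz) between a
  30 Hz standard and a comparison; start 10 Hz, 20 trials, switch after 10.
* ``temporal_order_judgement`` — stimulus onset asynchrony (ms) between
  two sequential pulses; start 150 ms, multiplicative ±10% steps,
  one-up–one-down throughout, 20 trials.

Every tracked run is preceded by a practice gate: blocks of three trials
at the starting value that must all be answered correctly before the
staircase begins.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

DETECTION = "detection"
AMPLITUDE = "amplitude_discrimination"
FREQUENCY = "frequency_discrimination"
TOJ = "temporal_order_judgement"
PROTOCOLS = (DETECTION, AMPLITUDE, FREQUENCY, TOJ)

SITES = ("d2", "d3")

#: Unit of the tracked variable, per protocol.
TRACKED_UNITS = {DETECTION: "um", AMPLITUDE: "um", FREQUENCY: "hz", TOJ: "ms"}


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


class PracticeGateError(RuntimeError):
    """Responder failed the three-consecutive-correct practice gate."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Full parameterization of one staircase protocol.

    ``limits`` bound the tracked variable at all times (the stimulator
    operates between 0–350 μm and 0–50 Hz; discrimination limits are
    expressed on the difference scale so the comparison stimulus stays
    inside the device range and above the standard).
    """

    protocol_id: str
    tracked_variable: str
    start_value: float
    step_mode: str  # "additive" | "multiplicative"
    step: float
    n_trials: int
    rule_switch_trial: int | None
    limits: tuple[float, float]
    standard_value: float | None = None
    stimulus: dict = field(default_factory=dict)
    iti_s: float = 5.0

    def __post_init__(self) -> None:
        if self.protocol_id not in PROTOCOLS:
            raise ProtocolError(f"unknown protocol_id {self.protocol_id!r}")
        if self.step_mode not in ("additive", "multiplicative"):
            raise ProtocolError(f"unknown step_mode {self.step_mode!r}")
        if self.step <= 0:
            raise ProtocolError("step must be positive")
        if self.step_mode == "multiplicative" and not (0 < self.step < 1):
            raise ProtocolError("multiplicative step must lie in (0, 1)")
        lo, hi = self.limits
        if not (lo <= self.start_value <= hi):
            raise ProtocolError(
                f"start_value {self.start_value} outside limits {self.limits}"
            )
        if lo < 0:
            raise ProtocolError("tracked variable cannot go negative")
        # a threshold is the mean of the final five trials, so a run
        # needs at least five tracked trials plus one to move from
        if self.n_trials < 6:
            raise ProtocolError("n_trials must be at least 6")
        if self.rule_switch_trial is not None and self.rule_switch_trial < 1:
            raise ProtocolError("rule_switch_trial must be >= 1 or None")

    @property
    def units(self) -> str:
        return TRACKED_UNITS[self.protocol_id]


_DEFAULTS: dict[str, dict] = {
    DETECTION: dict(
        tracked_variable="stimulus_amplitude_um",
        start_value=20.0,
        step_mode="additive",
        step=2.0,  # not specified by the protocol; 2 μm reaches child thresholds within 24 trials
        n_trials=24,
        rule_switch_trial=10,
        limits=(1.0, 350.0),  # a stimulus must always exist, hence the 1 μm floor
        standard_value=None,
        stimulus=dict(carrier_frequency_hz=25.0, duration_ms=500.0),
        iti_s=5.0,
    ),
    AMPLITUDE: dict(
        tracked_variable="amplitude_difference_um",
        start_value=100.0,  # comparison starts at 200 μm against the 100 μm standard
        step_mode="additive",
        step=10.0,
        n_trials=20,
        rule_switch_trial=10,
        limits=(10.0, 250.0),  # comparison = standard + difference must stay <= 350 μm
        standard_value=100.0,
        stimulus=dict(carrier_frequency_hz=25.0, duration_ms=500.0),
        iti_s=5.0,
    ),
    FREQUENCY: dict(
        tracked_variable="frequency_difference_hz",
        start_value=10.0,  # comparison starts at 40 Hz against the 30 Hz standard
        step_mode="additive",
        step=1.0,
        n_trials=20,
        rule_switch_trial=10,
        limits=(1.0, 20.0),  # comparison must exceed the standard and stay <= 50 Hz
        standard_value=30.0,
        stimulus=dict(amplitude_um=200.0, duration_ms=500.0),
        iti_s=5.0,
    ),
    TOJ: dict(
        tracked_variable="soa_ms",
        start_value=150.0,
        step_mode="multiplicative",
        step=0.10,
        n_trials=20,
        rule_switch_trial=None,  # one-up–one-down throughout
        limits=(1.0, 500.0),
        standard_value=None,
        stimulus=dict(carrier_frequency_hz=25.0, pulse_duration_ms=40.0,
                      amplitude_um=200.0),
        iti_s=5.0,
    ),
}


def make_protocol(protocol_id: str, overrides: dict | None = None) -> ProtocolSpec:
    """Return the default :class:`ProtocolSpec` with ``overrides`` applied."""
    if protocol_id not in _DEFAULTS:
        raise ProtocolError(f"unknown protocol_id {protocol_id!r}")
    params = dict(_DEFAULTS[protocol_id])
    overrides = dict(overrides or {})
    for key in overrides:
        if key == "protocol_id":
            raise ProtocolError("protocol_id cannot be overridden")
        if key not in params:
            raise ProtocolError(f"unknown override {key!r} for {protocol_id}")
    if "limits" in overrides:
        overrides["limits"] = tuple(overrides["limits"])
    params.update(overrides)
    return ProtocolSpec(protocol_id=protocol_id, **params)


def default_protocols() -> dict[str, ProtocolSpec]:
    """Default spec for every protocol in the battery."""
    return {pid: make_protocol(pid) for pid in PROTOCOLS}


@dataclass(frozen=True)
class StaircaseState:
    """State of the tracker *before* presenting trial ``trial_index`` (1-based)."""

    current_value: float
    trial_index: int = 1
    consecutive_correct: int = 0
    last_direction: str = "none"  # "down" | "up" | "none"


@dataclass(frozen=True, slots=True)
class Trial:
    trial_index: int
    tracked_value: float
    target_site: str
    response_site: str
    correct: bool
    rt_ms: float
    is_practice: bool


@dataclass
class TrialLog:
    """Ordered trial record of one participant × protocol run."""

    participant_id: str
    protocol_id: str
    trials: list[Trial]
    seed: int

    def tracked_values(self, include_practice: bool = False) -> list[float]:
        return [t.tracked_value for t in self.trials
                if include_practice or not t.is_practice]


def staircase_update(state: StaircaseState, spec: ProtocolSpec,
                     correct: bool) -> StaircaseState:
    """Advance the staircase by one response.

    Trials up to and including ``rule_switch_trial`` follow one-up–one-down
    (every correct response steps down, every error steps up). Afterwards a
    two-correct rule applies: a step down requires two consecutive correct
    responses (the counter then resets), while any error steps up
    immediately. Additive trackers move by ``±step``; multiplicative
    trackers scale by ``1 ∓ step``. Values are clamped to ``spec.limits``.
    """
    one_up_one_down = (spec.rule_switch_trial is None
                       or state.trial_index <= spec.rule_switch_trial)
    direction: str | None = None
    streak = state.consecutive_correct
    if one_up_one_down:
        direction = "down" if correct else "up"
        streak = 0
    elif correct:
        streak += 1
        if streak >= 2:
            direction = "down"
            streak = 0
    else:
        direction = "up"
        streak = 0

    value = state.current_value
    last = state.last_direction
    if direction is not None:
        if spec.step_mode == "additive":
            value = value - spec.step if direction == "down" else value + spec.step
        else:
            value = value * (1.0 - spec.step) if direction == "down" \
                else value * (1.0 + spec.step)
        lo, hi = spec.limits
        value = lo if value < lo else hi if value > hi else value
        last = direction
    return StaircaseState(value, state.trial_index + 1, streak, last)


def run_protocol(spec: ProtocolSpec, responder, rng_seed: int,
                 participant_id: str = "sim",
                 max_practice_attempts: int = 10) -> TrialLog:
    """Execute one full protocol run against ``responder``.

    ``responder`` must expose
    ``respond(protocol_id, tracked_value, target_site, rng) ->
    (response_site, correct, rt_ms)``; see :mod:`tactsim.observer`.

    The practice gate presents blocks of three trials at the starting
    value and repeats until a block is fully correct; the gate gives up
    after ``max_practice_attempts`` blocks and raises
    :class:`PracticeGateError` for a non-compliant responder. Target
    sites are pseudorandomized as independent fair coin flips.
    """
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    trials: list[Trial] = []
    index = 1

    passed = False
    for _attempt in range(max_practice_attempts):
        block_ok = True
        for _ in range(3):
            target = SITES[rng.random() < 0.5]
            site, correct, rt = responder.respond(
                spec.protocol_id, spec.start_value, target, rng)
            trials.append(Trial(index, spec.start_value, target, site,
                                correct, rt, True))
            index += 1
            block_ok = block_ok and correct
        if block_ok:
            passed = True
            break
    if not passed:
        raise PracticeGateError(
            f"{participant_id}/{spec.protocol_id}: practice gate not passed "
            f"in {max_practice_attempts} attempts")

    state = StaircaseState(spec.start_value)
    for _ in range(spec.n_trials):
        target = SITES[rng.random() < 0.5]
        site, correct, rt = responder.respond(
            spec.protocol_id, state.current_value, target, rng)
        trials.append(Trial(index, state.current_value, target, site,
                            correct, rt, False))
        index += 1
        state = staircase_update(state, spec, correct)
    return TrialLog(participant_id, spec.protocol_id, trials, int(rng_seed))


def count_reversals(values: Sequence[float]) -> int:
    """Number of sign changes in the sequence of non-zero steps of ``values``."""
    signs = []
    for prev, curr in zip(values, values[1:]):
        d = curr - prev
        if d != 0:
            signs.append(1 if d > 0 else -1)
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def detect_reversals(log: TrialLog) -> int:
    """Reversal count over the non-practice trials of ``log``.

    A reversal is counted whenever the tracked variable changes direction;
    trials on which the value did not move (two-correct holds, clamping at
    the limits) are transparent to the count.
    """
    if not log.trials:
        raise ValueError("empty trial log")
    return count_reversals(log.tracked_values())


# ---------------------------------------------------------------------------
# trial-log CSV dialect

_LOG_COLUMNS = ["participant_id", "protocol_id", "trial_index", "is_practice",
                "tracked_value", "units", "target_site", "response_site",
                "correct", "rt_ms", "seed"]


def trial_logs_to_frame(logs: Iterable[TrialLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        units = TRACKED_UNITS[log.protocol_id]
        for t in log.trials:
            rows.append((log.participant_id, log.protocol_id, t.trial_index,
                         t.is_practice, t.tracked_value, units, t.target_site,
                         t.response_site, t.correct, t.rt_ms, log.seed))
    return pd.DataFrame(rows, columns=_LOG_COLUMNS)


def write_trial_logs(logs: Iterable[TrialLog], path) -> None:
    """Write one or more runs to the trial-log CSV dialect."""
    trial_logs_to_frame(logs).to_csv(path, index=False)


def read_trial_logs(path) -> list[TrialLog]:
    """Read runs back from the trial-log CSV dialect."""
    df = pd.read_csv(path)
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial-log CSV missing columns: {sorted(missing)}")
    logs = []
    for (pid, proto), grp in df.groupby(["participant_id", "protocol_id"],
                                        sort=False):
        grp = grp.sort_values("trial_index")
        trials = [Trial(int(r.trial_index), float(r.tracked_value),
                        str(r.target_site), str(r.response_site),
                        bool(r.correct), float(r.rt_ms), bool(r.is_practice))
                  for r in grp.itertuples()]
        logs.append(TrialLog(str(pid), str(proto), trials,
                             int(grp["seed"].iloc[0])))
    return logs
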