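"""Reduce trial logs to per-run outcomes: threshold, RT, accuracy, reversals.

The tracking estimate of the threshold is the arithmetic mean of the
tracked variable over the final five non-practice trials (the values
actually presented; the post-update value after the last response never
contributes). Accuracy and median reaction time are computed over all
non-practice trials. Practice trials are excluded from every outcome.
"""
from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable

import pandas as pd

from .protocols import ProtocolSpec, TrialLog, count_reversals


class IncompleteRunError(ValueError):
    """Run has too few tracked trials to yield a threshold."""


@dataclass(frozen=True)
class ThresholdEstimate:
    participant_id: str
    protocol_id: str
    threshold: float
    accuracy: float
    median_rt_ms: float
    n_reversals: int
    n_trials_used: int


def estimate_threshold(log: TrialLog,
                       spec: ProtocolSpec | None = None) -> ThresholdEstimate:
    """Tracking outcomes for one run.

    Requires at least five non-practice trials; when ``spec`` is given the
    run must additionally contain exactly ``spec.n_trials`` tracked trials.
    """
    tracked = [t for t in log.trials if not t.is_practice]
    if len(tracked) < 5:
        raise IncompleteRunError(
            f"{log.participant_id}/{log.protocol_id}: "
            f"{len(tracked)} tracked trials, need >= 5")
    if spec is not None and len(tracked) != spec.n_trials:
        raise IncompleteRunError(
            f"{log.participant_id}/{log.protocol_id}: expected "
            f"{spec.n_trials} tracked trials, found {len(tracked)}")
    values = [t.tracked_value for t in tracked]
    threshold = sum(values[-5:]) / 5.0
    accuracy = sum(t.correct for t in tracked) / len(tracked)
    med_rt = float(median(t.rt_ms for t in tracked))
    return ThresholdEstimate(
        participant_id=log.participant_id,
        protocol_id=log.protocol_id,
        threshold=threshold,
        accuracy=accuracy,
        median_rt_ms=med_rt,
        n_reversals=count_reversals(values),
        n_trials_used=len(tracked),
    )


OUTCOME_COLUMNS = ["participant_id", "protocol_id", "threshold", "accuracy",
                   "median_rt_ms", "n_reversals", "n_trials_used"]


def process_cohort(logs: Iterable[TrialLog],
                   specs: dict[str, ProtocolSpec] | None = None) -> pd.DataFrame:
    """Tidy outcome table: one row per participant × protocol.

    Protocols a participant never ran simply yield no row — outcomes are
    never imputed. Duplicate participant × protocol runs are rejected.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for log in logs:
        key = (log.participant_id, log.protocol_id)
        if key in seen:
            raise ValueError(f"duplicate run for {key}")
        seen.add(key)
        spec = specs.get(log.protocol_id) if specs else None
        est = estimate_threshold(log, spec)
        rows.append(tuple(getattr(est, c) for c in OUTCOME_COLUMNS))
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
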