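"""Generative 2AFC responder: psychometric function, lapses, reaction times.

Each simulated participant carries one parameter set per protocol. The
probability of a correct response at tracked level ``x`` follows the
standard high-threshold 2AFC model

    p(x) = guess + (1 - guess - lapse) * F((x - theta) / sigma)

with ``F`` the cumulative Gaussian, ``guess = 0.5`` (two alternatives),
``theta`` the latent sensory threshold in tracked units and ``sigma`` the
slope scale. ``lapse`` caps asymptotic performance at ``1 - lapse``.
Reaction times are drawn from a log-normal that is independent of
correctness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .protocols import PROTOCOLS, SITES

_SQRT2 = math.sqrt(2.0)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@dataclass(frozen=True)
class ChannelParams:
    """Observer parameters for a single protocol.

    theta, sigma are in the tracked units of that protocol (μm, Hz or ms).
    """

    theta: float
    sigma: float
    lapse: float = 0.02
    guess: float = 0.5
    rt_median_ms: float = 800.0
    rt_spread: float = 0.35

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.rt_median_ms <= 0 or self.rt_spread <= 0:
            raise ValueError("reaction-time parameters must be positive")


@dataclass
class Observer:
    """Per-protocol generative response model for one participant."""

    channels: dict[str, ChannelParams] = field(default_factory=dict)

    def p_correct(self, protocol_id: str, x: float) -> float:
        return p_correct(self, protocol_id, x)

    def respond(self, protocol_id: str, tracked_value: float,
                target_site: str, rng) -> tuple[str, bool, float]:
        return respond(self, protocol_id, tracked_value, target_site, rng)


def p_correct(observer: Observer, protocol_id: str, x: float) -> float:
    """Probability of a correct 2AFC response at tracked level ``x``.

    Monotone non-decreasing in ``x``; bounded in
    ``[guess, 1 - lapse]``. ``sigma == 0`` is the step-function limit
    (chance below threshold, asymptote above, midpoint at threshold).
    """
    if x < 0:
        raise ValueError("stimulus level must be non-negative")
    ch = observer.channels[protocol_id]
    if ch.sigma == 0.0:
        f = 0.5 if x == ch.theta else float(x > ch.theta)
    else:
        f = _norm_cdf((x - ch.theta) / ch.sigma)
    return ch.guess + (1.0 - ch.guess - ch.lapse) * f


def respond(observer: Observer, protocol_id: str, tracked_value: float,
            target_site: str, rng) -> tuple[str, bool, float]:
    """Draw one response: site chosen, correctness, reaction time in ms."""
    ch = observer.channels[protocol_id]
    p = p_correct(observer, protocol_id, tracked_value)
    correct = rng.random() < p
    if correct:
        site = target_site
    else:
        site = SITES[0] if target_site == SITES[1] else SITES[1]
    rt = ch.rt_median_ms * math.exp(ch.rt_spread * rng.standard_normal())
    return site, bool(correct), rt


def make_observer(theta: dict[str, float], sigma: dict[str, float],
                  lapse: float = 0.02, rt_median_ms: float = 800.0,
                  rt_spread: float = 0.35) -> Observer:
    """Convenience constructor from per-protocol theta/sigma maps."""
    channels = {
        pid: ChannelParams(theta=theta[pid], sigma=sigma[pid], lapse=lapse,
                           rt_median_ms=rt_median_ms, rt_spread=rt_spread)
        for pid in theta
    }
    return Observer(channels)


class DeterministicResponder:
    """Responder that is always correct (or always incorrect). Test utility."""

    def __init__(self, correct: bool, rt_ms: float = 500.0):
        self.correct = bool(correct)
        self.rt_ms = float(rt_ms)

    def respond(self, protocol_id, tracked_value, target_site, rng):
        if self.correct:
            site = target_site
        else:
            site = SITES[0] if target_site == SITES[1] else SITES[1]
        return site, self.correct, self.rt_ms


class ScriptedResponder:
    """Replays a fixed boolean response sequence (ignores the stimulus)."""

    def __init__(self, responses, practice_correct: bool = True,
                 rt_ms: float = 500.0):
        self.responses = list(responses)
        self.practice_correct = practice_correct
        self.rt_ms = float(rt_ms)
        self._practice_left = 3 if practice_correct else 0
        self._i = 0

    def respond(self, protocol_id, tracked_value, target_site, rng):
        if self._practice_left > 0:
            self._practice_left -= 1
            correct = True
        else:
            correct = self.responses[self._i]
            self._i += 1
        if correct:
            site = target_site
        else:
            site = SITES[0] if target_site == SITES[1] else SITES[1]
        return site, bool(correct), self.rt_ms
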