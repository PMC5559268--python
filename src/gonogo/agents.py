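"""Synthetic behavioral agents.

Stand-ins for mice (or humans) that emit lick trains with controlled
statistical structure, so that every analysis stage can be exercised and
calibrated without animal data:

* :class:`RandomLicker` — licks with a fixed probability regardless of the
  stimulus; the null agent behind chance calibration ("a randomly
  performing mouse that licked on 90% of trials").
* :class:`ParametricAgent` — direct control of hit and false-alarm rates.
* :class:`TransitionDetector` — an idealised observer that reads the
  amplitude envelope, detects the first syllable where GO and NO-GO
  envelopes diverge, and on GO trials starts sustained licking a
  configurable decision latency after that divergence.

Lick trains are modeled as a regular train at ``lick_rate_hz`` (default
7 Hz, typical rodent licking) with optional Gaussian jitter per lick; the
downstream analyses consume binned rates and are insensitive to fine train
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimuli import AmplitudeEnvelope
from .task import GO, NOGO

__all__ = [
    "AgentParams",
    "RandomLicker",
    "ParametricAgent",
    "TransitionDetector",
    "divergence_time_ms",
    "lick_train",
    "make_agent",
]

DEFAULT_LICK_RATE_HZ = 7.0
DEFAULT_RESPONSE_WINDOW_MS = (800.0, 2300.0)


def lick_train(
    start_ms: float,
    stop_ms: float,
    rate_hz: float,
    jitter_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Regular lick train on [start, stop] ms with per-lick Gaussian jitter."""
    if stop_ms < start_ms or rate_hz <= 0:
        return np.empty(0)
    period_ms = 1000.0 / rate_hz
    times = np.arange(start_ms, stop_ms + 1e-9, period_ms)
    if jitter_ms > 0:
        times = times + rng.normal(0.0, jitter_ms, size=times.shape)
    return np.sort(np.clip(times, 0.0, None))


def divergence_time_ms(
    go_envelope: AmplitudeEnvelope, nogo_envelope: AmplitudeEnvelope
) -> float:
    """Time of the first syllable where the two envelopes differ.

    This is the earliest moment an instantaneous ideal observer could in
    principle determine sequence identity.
    """
    if go_envelope.syllable_ms != nogo_envelope.syllable_ms:
        raise ValueError("envelopes must share syllable duration")
    n = min(len(go_envelope), len(nogo_envelope))
    for i in range(n):
        if go_envelope.levels[i] != nogo_envelope.levels[i]:
            return i * go_envelope.syllable_ms
    if len(go_envelope) != len(nogo_envelope):
        return n * go_envelope.syllable_ms
    raise ValueError("envelopes are identical; no discriminative evidence exists")


@dataclass
class RandomLicker:
    """Licks with probability ``lick_prob`` independent of the stimulus."""

    lick_prob: float
    lick_rate_hz: float = DEFAULT_LICK_RATE_HZ
    jitter_ms: float = 10.0
    response_window_ms: tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS

    def __post_init__(self) -> None:
        if not 0 <= self.lick_prob <= 1:
            raise ValueError("lick_prob must be in [0, 1]")

    def lick_times(self, stimulus_class: str, rng: np.random.Generator) -> np.ndarray:
        if rng.random() >= self.lick_prob:
            return np.empty(0)
        start, stop = self.response_window_ms
        return lick_train(start, stop, self.lick_rate_hz, self.jitter_ms, rng)


@dataclass
class ParametricAgent:
    """Responds with probability ``hit_rate`` on GO, ``fa_rate`` on NO-GO."""

    hit_rate: float
    fa_rate: float
    lick_rate_hz: float = DEFAULT_LICK_RATE_HZ
    jitter_ms: float = 10.0
    response_window_ms: tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS

    def __post_init__(self) -> None:
        if not (0 <= self.hit_rate <= 1 and 0 <= self.fa_rate <= 1):
            raise ValueError("hit_rate and fa_rate must be in [0, 1]")

    def lick_times(self, stimulus_class: str, rng: np.random.Generator) -> np.ndarray:
        p = self.hit_rate if stimulus_class == GO else self.fa_rate
        if rng.random() >= p:
            return np.empty(0)
        start, stop = self.response_window_ms
        return lick_train(start, stop, self.lick_rate_hz, self.jitter_ms, rng)


@dataclass
class TransitionDetector:
    """Idealised sequence recogniser with a configurable decision latency.

    Reads amplitude levels instantaneously and noiselessly per syllable.
    On GO trials it begins sustained licking at
    ``divergence + decision_latency_ms`` (the divergence being the first
    syllable where the GO and NO-GO envelopes differ) and keeps licking to
    the end of the response window.  On NO-GO trials it licks with
    probability ``fa_rate`` (spanning the response window), modeling
    occasional impulsive responses.
    """

    go_envelope: AmplitudeEnvelope
    nogo_envelope: AmplitudeEnvelope
    decision_latency_ms: float = 0.0
    fa_rate: float = 0.1
    lick_rate_hz: float = DEFAULT_LICK_RATE_HZ
    jitter_ms: float = 0.0
    response_window_ms: tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS
    divergence_ms: float = field(init=False)

    def __post_init__(self) -> None:
        if self.decision_latency_ms < 0 or self.jitter_ms < 0:
            raise ValueError("decision_latency_ms and jitter_ms must be >= 0")
        if not 0 <= self.fa_rate <= 1:
            raise ValueError("fa_rate must be in [0, 1]")
        self.divergence_ms = divergence_time_ms(self.go_envelope, self.nogo_envelope)

    def lick_times(self, stimulus_class: str, rng: np.random.Generator) -> np.ndarray:
        _, stop = self.response_window_ms
        if stimulus_class == GO:
            start = self.divergence_ms + self.decision_latency_ms
            return lick_train(start, stop, self.lick_rate_hz, self.jitter_ms, rng)
        if rng.random() < self.fa_rate:
            start, stop = self.response_window_ms
            return lick_train(start, stop, self.lick_rate_hz, self.jitter_ms, rng)
        return np.empty(0)


@dataclass(frozen=True)
class AgentParams:
    """Serializable agent specification (for configs and the CLI)."""

    kind: str
    lick_prob: float = 0.9
    hit_rate: float = 0.9
    fa_rate: float = 0.1
    decision_latency_ms: float = 100.0
    lick_rate_hz: float = DEFAULT_LICK_RATE_HZ
    jitter_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("random_licker", "parametric", "transition_detector"):
            raise ValueError(f"unknown agent kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lick_prob": self.lick_prob,
            "hit_rate": self.hit_rate,
            "fa_rate": self.fa_rate,
            "decision_latency_ms": self.decision_latency_ms,
            "lick_rate_hz": self.lick_rate_hz,
            "jitter_ms": self.jitter_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        return cls(**d)


def make_agent(
    params: AgentParams,
    go_envelope: AmplitudeEnvelope | None = None,
    nogo_envelope: AmplitudeEnvelope | None = None,
    response_window_ms: tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
):
    """Instantiate the agent described by ``params``."""
    if params.kind == "random_licker":
        return RandomLicker(
            lick_prob=params.lick_prob,
            lick_rate_hz=params.lick_rate_hz,
            jitter_ms=params.jitter_ms,
            response_window_ms=response_window_ms,
        )
    if params.kind == "parametric":
        return ParametricAgent(
            hit_rate=params.hit_rate,
            fa_rate=params.fa_rate,
            lick_rate_hz=params.lick_rate_hz,
            jitter_ms=params.jitter_ms,
            response_window_ms=response_window_ms,
        )
    if go_envelope is None or nogo_envelope is None:
        raise ValueError("transition_detector needs both envelopes")
    return TransitionDetector(
        go_envelope=go_envelope,
        nogo_envelope=nogo_envelope,
        decision_latency_ms=params.decision_latency_ms,
        fa_rate=params.fa_rate,
        lick_rate_hz=params.lick_rate_hz,
        jitter_ms=params.jitter_ms,
        response_window_ms=response_window_ms,
    )
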