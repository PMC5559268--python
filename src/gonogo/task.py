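"""GO/NO-GO trial engine.

A trial is a 0.8 s stimulation period followed by a 1.5 s response period.
Licking within the response period on a GO trial is a hit (rewarded with a
water droplet); failing to lick is a miss.  On a NO-GO trial withholding is
a correct rejection and licking is a false alarm, which delays the next
trial by 2-5 s.  Licks during stimulation are recorded but do not by
themselves set the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "GO",
    "NOGO",
    "OUTCOMES",
    "TaskConfig",
    "TrialRecord",
    "SessionLog",
    "classify_outcome",
    "run_session",
]

GO = "GO"
NOGO = "NOGO"
OUTCOMES = ("hit", "miss", "correct_rejection", "false_alarm")


@dataclass(frozen=True)
class TaskConfig:
    """Timing and scheduling parameters of a session.

    Durations are in seconds. ``fa_delay_range_s`` is the uniform range of
    the extra delay imposed after a false alarm. ``iti_s`` is the baseline
    inter-trial interval (bookkeeping only; no value is canonical).
    """

    stimulation_s: float = 0.8
    response_s: float = 1.5
    fa_delay_range_s: tuple[float, float] = (2.0, 5.0)
    go_fraction: float = 0.5
    n_trials: int = 250
    iti_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stimulation_s <= 0 or self.response_s <= 0:
            raise ValueError("stimulation_s and response_s must be positive")
        lo, hi = self.fa_delay_range_s
        if lo > hi:
            raise ValueError("fa_delay_range_s min must be <= max")
        if not 0 < self.go_fraction < 1:
            raise ValueError("go_fraction must be in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        object.__setattr__(self, "fa_delay_range_s", (float(lo), float(hi)))

    @property
    def trial_duration_ms(self) -> float:
        return 1000.0 * (self.stimulation_s + self.response_s)

    @property
    def response_window_ms(self) -> tuple[float, float]:
        """Response window [start, end] in ms from stimulus onset."""
        start = 1000.0 * self.stimulation_s
        return (start, start + 1000.0 * self.response_s)

    def to_dict(self) -> dict:
        return {
            "stimulation_s": self.stimulation_s,
            "response_s": self.response_s,
            "fa_delay_range_s": list(self.fa_delay_range_s),
            "go_fraction": self.go_fraction,
            "n_trials": self.n_trials,
            "iti_s": self.iti_s,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "fa_delay_range_s" in d:
            d["fa_delay_range_s"] = tuple(d["fa_delay_range_s"])
        return cls(**d)


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial."""

    index: int
    stimulus_class: str
    stimulus_id: str
    lick_times_ms: tuple[float, ...]
    outcome: str
    rewarded: bool
    next_trial_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.stimulus_class not in (GO, NOGO):
            raise ValueError(f"unknown stimulus class {self.stimulus_class!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        go_outcome = self.outcome in ("hit", "miss")
        if go_outcome != (self.stimulus_class == GO):
            raise ValueError(
                f"outcome {self.outcome!r} inconsistent with class "
                f"{self.stimulus_class!r}"
            )
        if self.rewarded != (self.outcome == "hit"):
            raise ValueError("rewarded must hold exactly on hit trials")

    @property
    def licked(self) -> bool:
        """Whether the trial counted as a lick response."""
        return self.outcome in ("hit", "false_alarm")


@dataclass
class SessionLog:
    """Ordered trials of one subject's session; the unit of all analyses."""

    subject_id: str
    task_tag: str
    trials: list[TrialRecord]
    config: TaskConfig

    def __len__(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        indices = [t.index for t in self.trials]
        if indices != list(range(1, len(self.trials) + 1)):
            raise ValueError("trial indices must be contiguous from 1")


class Agent(Protocol):
    """Behavioral agent contract: emit sorted, non-negative lick times (ms)."""

    def lick_times(
        self, stimulus_class: str, rng: np.random.Generator
    ) -> np.ndarray: ...


def classify_outcome(
    stimulus_class: str,
    lick_times_ms: Sequence[float],
    config: TaskConfig,
) -> str:
    """Outcome from the presence of a lick inside the response window.

    The window is [stimulation end, stimulation end + response period]; a
    lick exactly at stimulus offset counts as within the response period.
    """
    licks = np.asarray(lick_times_ms, dtype=float)
    if licks.size:
        if np.any(licks < 0):
            raise ValueError("lick times must be non-negative")
        if np.any(np.diff(licks) < 0):
            raise ValueError("lick times must be sorted ascending")
    start, end = config.response_window_ms
    responded = bool(np.any((licks >= start) & (licks <= end)))
    if stimulus_class == GO:
        return "hit" if responded else "miss"
    if stimulus_class == NOGO:
        return "false_alarm" if responded else "correct_rejection"
    raise ValueError(f"unknown stimulus class {stimulus_class!r}")


def run_session(
    agent: Agent,
    config: TaskConfig,
    stimulus_ids: tuple[str, str] = ("GO", "full-NOGO"),
    schedule: Sequence[str] | None = None,
    subject_id: str = "sim",
    task_tag: str = "GO-vs-fullNOGO",
) -> SessionLog:
    """Run ``config.n_trials`` trials of an agent and log the outcomes.

    GO/NO-GO assignment is i.i.d. Bernoulli(``go_fraction``) unless an
    explicit ``schedule`` of class labels is given.  Deterministic for a
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if schedule is not None:
        if len(schedule) != config.n_trials:
            raise ValueError("schedule length must equal n_trials")
        classes = [str(c) for c in schedule]
        if any(c not in (GO, NOGO) for c in classes):
            raise ValueError("schedule entries must be GO or NOGO")
    else:
        classes = [GO if u < config.go_fraction else NOGO
                   for u in rng.random(config.n_trials)]

    go_id, nogo_id = stimulus_ids
    trials: list[TrialRecord] = []
    for i, cls in enumerate(classes, start=1):
        licks = np.sort(np.asarray(agent.lick_times(cls, rng), dtype=float))
        if licks.size and licks[0] < 0:
            raise ValueError(
                f"agent emitted a negative lick time on trial {i}: {licks[0]}"
            )
        outcome = classify_outcome(cls, licks, config)
        delay = 0.0
        if outcome == "false_alarm":
            delay = float(rng.uniform(*config.fa_delay_range_s))
        trials.append(
            TrialRecord(
                index=i,
                stimulus_class=cls,
                stimulus_id=go_id if cls == GO else nogo_id,
                lick_times_ms=tuple(float(t) for t in licks),
                outcome=outcome,
                rewarded=(outcome == "hit"),
                next_trial_delay_s=delay,
            )
        )
    return SessionLog(
        subject_id=subject_id, task_tag=task_tag, trials=trials, config=config
    )
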