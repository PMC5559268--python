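"""End-to-end pipeline: stimuli -> simulated session -> metrics report.

``run_pipeline`` wires the whole toolkit together and is fully reproducible
from (config, seed): sub-seeds for stimulus synthesis, the trial schedule
and the resampling statistics are all derived deterministically from the
run seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics, session_io, stimuli
from .agents import AgentParams, make_agent
from .stimuli import FULL_NOGO_ENVELOPE, GO_ENVELOPE, StimulusConfig
from .task import TaskConfig, run_session

__all__ = ["AnalysisConfig", "RunConfig", "analyze_session", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the statistical analyses."""

    window_size: int = 50
    n_shuffles: int = 10000
    n_repeats: int = 50
    alpha: float = 0.05
    bin_ms: float = 100.0
    smoothing_sd_ms: float = 50.0
    calibration_threshold_pct: float = 75.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a simulate-and-analyze run."""

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(
        default_factory=lambda: AgentParams(kind="transition_detector")
    )
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "."
    log_level: str = "info"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.analysis.window_size > self.task.n_trials:
            raise ValueError("analysis window_size must not exceed task n_trials")

    def to_dict(self) -> dict:
        return {
            "stimulus": self.stimulus.to_dict(),
            "task": self.task.to_dict(),
            "agent": self.agent.to_dict(),
            "analysis": self.analysis.to_dict(),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            stimulus=StimulusConfig.from_dict(d.get("stimulus", {})),
            task=TaskConfig.from_dict(d.get("task", {})),
            agent=AgentParams.from_dict(d.get("agent", {})),
            analysis=AnalysisConfig.from_dict(d.get("analysis", {})),
            output_dir=d.get("output_dir", "."),
            log_level=d.get("log_level", "info"),
            seed=int(d.get("seed", 0)),
        )


def _subseed(seed: int, k: int) -> int:
    # distinct deterministic streams per pipeline stage, kept below 2^31
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return None if math.isnan(obj) else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(float(obj), ndigits)
    return obj


def analyze_session(session, analysis: AnalysisConfig, seed: int = 0) -> dict:
    """Metrics report for one session: rates, d', performance, p, latency."""
    hit_rate, fa_rate = metrics.hit_fa_rates(session)
    n_go = sum(1 for t in session.trials if t.stimulus_class == "GO")
    n_nogo = len(session.trials) - n_go
    d = metrics.dprime(hit_rate, fa_rate, n_go, n_nogo)
    trace = metrics.sliding_performance(session, analysis.window_size, rebalanced=True)
    best_pct = float(np.nanmax(trace.percent_correct))
    calib = metrics.shuffle_calibration(
        session,
        threshold_pct=analysis.calibration_threshold_pct,
        window_size=analysis.window_size,
        n_shuffles=analysis.n_shuffles,
        rng=np.random.default_rng(_subseed(seed, 1)),
    )
    latency = metrics.discriminative_lick_latency(
        session,
        window_size=analysis.window_size,
        n_repeats=analysis.n_repeats,
        alpha=analysis.alpha,
        bin_ms=analysis.bin_ms,
        smoothing_sd_ms=analysis.smoothing_sd_ms,
        rng=np.random.default_rng(_subseed(seed, 2)),
    )
    return {
        "n_trials": len(session.trials),
        "n_go": n_go,
        "n_nogo": n_nogo,
        "hit_rate": hit_rate,
        "fa_rate": fa_rate,
        "dprime": d,
        "percent_correct_rebalanced": metrics.percent_correct(
            session.trials, rebalanced=True
        ),
        "percent_correct_raw": metrics.percent_correct(session.trials),
        "best_window_percent_correct": best_pct,
        "calibration": {
            "threshold_pct": calib.threshold_pct,
            "n_shuffles": calib.n_shuffles,
            "p_estimate": calib.p_estimate,
            "statistic": calib.statistic,
        },
        "discriminative_lick_latency_ms": latency.latency_ms,
        "latency_diagnostic": latency.diagnostic,
    }


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Generate stimuli, simulate a session, analyze it, write the report.

    Returns the report dict; when ``write_outputs`` is set, writes
    ``session.csv``, ``report.json`` and the GO/NO-GO waveforms (WAV) into
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    stim_cfg = dataclasses.replace(config.stimulus, seed=_subseed(config.seed, 10))
    go_wave = stimuli.assemble_sequence(GO_ENVELOPE, stim_cfg)
    nogo_wave = stimuli.assemble_sequence(FULL_NOGO_ENVELOPE, stim_cfg)

    task_cfg = dataclasses.replace(config.task, seed=_subseed(config.seed, 11))
    agent = make_agent(
        config.agent,
        go_envelope=GO_ENVELOPE,
        nogo_envelope=FULL_NOGO_ENVELOPE,
        response_window_ms=task_cfg.response_window_ms,
    )
    session = run_session(agent, task_cfg)
    report = {
        "config": config.to_dict(),
        "stimuli": {
            "GO": {
                "envelope": list(GO_ENVELOPE.levels),
                "duration_ms": go_wave.duration_ms,
                "empirical_sd": stimuli.empirical_sd(go_wave),
            },
            "full-NOGO": {
                "envelope": list(FULL_NOGO_ENVELOPE.levels),
                "duration_ms": nogo_wave.duration_ms,
                "empirical_sd": stimuli.empirical_sd(nogo_wave),
            },
        },
        "metrics": analyze_session(session, config.analysis, seed=config.seed),
    }
    report = _round_floats(report)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        session_io.write_session(session, out / "session.csv")
        stimuli.write_wav(go_wave, out / "go.wav")
        stimuli.write_wav(nogo_wave, out / "nogo.wav")
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
    return report
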