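"""Amplitude-modulated noise stimulus synthesis.

Stimuli are sequences of 100 ms "syllables": segments of white noise whose
amplitude is set by an integer level (1 = lowest, 4 = highest).  A sequence
is built by (1) drawing a 100 ms noise snippet at the actuator sampling
rate, (2) stitching eight snippets into a chain, (3) multiplying the chain
by the piecewise-constant amplitude envelope, (4) convolving with a Gaussian
(SD 1.64 ms) for frequency filtering, and (5) peak-normalising to the
actuator's dynamic range.  Under the *frozen* policy a single snippet is
reused for every syllable and every trial; under *unfrozen* each syllable
gets a fresh draw.

Envelope-level utilities (transitions, small/large epochs, scrambles,
syllable knockouts) operate on the integer level lists directly, since a
sequence's identity lives entirely in its envelope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "AmplitudeEnvelope",
    "StimulusConfig",
    "StimulusWaveform",
    "GO_ENVELOPE",
    "FULL_NOGO_ENVELOPE",
    "FULL_NOGO_ORDER",
    "BINARY_ENVELOPES",
    "n_samples",
    "make_snippet",
    "assemble_sequence",
    "gaussian_smooth",
    "normalize",
    "envelope_transitions",
    "envelope_epochs",
    "scramble_envelope",
    "knockout_syllables",
    "half_nogo_envelope",
    "square_wave_stimulus",
    "empirical_sd",
    "sd_matched",
    "write_wav",
    "write_waveform_csv",
]

# Internal tag mixed into the seed stream for the frozen snippet so the
# frozen draw is decoupled from per-trial draws made with the same seed.
_FROZEN_TAG = 0x46525A4E


@dataclass(frozen=True)
class AmplitudeEnvelope:
    """Ordered integer amplitude levels defining a sequence's identity.

    Parameters
    ----------
    levels
        One integer level (>= 1) per syllable.
    syllable_ms
        Syllable duration in milliseconds (default 100).
    """

    levels: tuple[int, ...]
    syllable_ms: float = 100.0

    def __post_init__(self) -> None:
        levels = tuple(int(v) for v in self.levels)
        if len(levels) < 1:
            raise ValueError("envelope needs at least one syllable")
        if any(v < 1 for v in levels):
            raise ValueError(f"amplitude levels must be integers >= 1, got {levels}")
        if self.syllable_ms <= 0:
            raise ValueError("syllable_ms must be positive")
        object.__setattr__(self, "levels", levels)

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def duration_ms(self) -> float:
        return len(self.levels) * self.syllable_ms


#: The target (rewarded) sequence.
GO_ENVELOPE = AmplitudeEnvelope((3, 1, 4, 2, 3, 1, 4, 2))
#: The final-stage distractor: the same syllables, temporally scrambled.
FULL_NOGO_ENVELOPE = AmplitudeEnvelope((3, 4, 2, 1, 2, 4, 3, 1))
#: Permutation mapping GO_ENVELOPE onto FULL_NOGO_ENVELOPE
#: (FULL_NOGO.levels[i] == GO.levels[FULL_NOGO_ORDER[i]]).
FULL_NOGO_ORDER = (0, 2, 3, 1, 7, 6, 4, 5)

#: Two-level (binary) variants used to probe which envelope features carry
#: the discrimination: same transition structure, different epoch durations.
BINARY_ENVELOPES = {
    "binary-GO": AmplitudeEnvelope((4, 1, 4, 1, 1, 1, 4, 1)),
    "binary-NOGO-epochs": AmplitudeEnvelope((4, 1, 1, 1, 4, 1, 4, 1)),
    "binary-NOGO-late": AmplitudeEnvelope((4, 1, 1, 1, 1, 1, 4, 4)),
    "binary-NOGO-single": AmplitudeEnvelope((4, 1, 1, 1, 1, 1, 1, 1)),
    "constant-low": AmplitudeEnvelope((1,) * 8),
    "constant-high": AmplitudeEnvelope((4,) * 8),
}


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of waveform synthesis.

    ``sample_rate_hz`` and ``filter_sd_ms`` default to the actuator values
    used throughout (12207 Hz; Gaussian SD 1.64 ms). ``base_gain`` converts
    one envelope level unit into a pre-normalisation amplitude multiplier;
    the mapping is linear in level. ``norm_peak`` is the post-normalisation
    peak absolute amplitude in actuator-drive units.
    """

    sample_rate_hz: float = 12207.0
    filter_sd_ms: float = 1.64
    snippet_policy: str = "frozen"
    base_gain: float = 1.0
    norm_peak: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.filter_sd_ms < 0:
            raise ValueError("filter_sd_ms must be non-negative")
        if self.norm_peak <= 0:
            raise ValueError("norm_peak must be positive")
        if self.snippet_policy not in ("frozen", "unfrozen"):
            raise ValueError(f"unknown snippet_policy {self.snippet_policy!r}")

    def to_dict(self) -> dict:
        return {
            "sample_rate_hz": self.sample_rate_hz,
            "filter_sd_ms": self.filter_sd_ms,
            "snippet_policy": self.snippet_policy,
            "base_gain": self.base_gain,
            "norm_peak": self.norm_peak,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusConfig":
        return cls(**d)


@dataclass(frozen=True)
class StimulusWaveform:
    """A sampled stimulus with its provenance.

    ``samples`` are normalised actuator-drive units; ``prefilter`` keeps the
    envelope-multiplied chain before filtering/normalisation, which is what
    energy-conservation arguments about scrambled sequences refer to.
    """

    samples: np.ndarray
    sample_rate_hz: float
    envelope: AmplitudeEnvelope | None
    policy_tag: str
    seed: int
    prefilter: np.ndarray = field(repr=False, default=None)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration_s


def n_samples(duration_ms: float, sample_rate_hz: float) -> int:
    """Sample count for a duration: round half away from zero."""
    return int(math.floor(duration_ms / 1000.0 * sample_rate_hz + 0.5))


def make_snippet(
    duration_ms: float, config: StimulusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one white-noise snippet: zero-mean, unit-SD Gaussian samples."""
    if duration_ms <= 0:
        raise ValueError(f"snippet duration must be positive, got {duration_ms} ms")
    return rng.standard_normal(n_samples(duration_ms, config.sample_rate_hz))


def gaussian_smooth(
    samples: np.ndarray, sd_ms: float, sample_rate_hz: float
) -> np.ndarray:
    """Convolve with a unit-sum Gaussian kernel (SD in ms).

    Kernel truncated at +/-4 SD; edges handled by reflection so that a
    constant input passes through unchanged. ``sd_ms = 0`` is the identity.
    """
    if sd_ms < 0:
        raise ValueError("sd_ms must be non-negative")
    x = np.asarray(samples, dtype=float)
    if sd_ms == 0:
        return x.copy()
    sigma = sd_ms / 1000.0 * sample_rate_hz
    return gaussian_filter1d(x, sigma, mode="reflect", truncate=4.0)


def normalize(samples: np.ndarray, norm_peak: float = 1.0) -> np.ndarray:
    """Scale so the maximum absolute value equals ``norm_peak``."""
    x = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0:
        raise ValueError("cannot normalize an all-zero waveform (undefined scale)")
    return x * (norm_peak / peak)


def _frozen_rng(config: StimulusConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _FROZEN_TAG])


def assemble_sequence(
    envelope: AmplitudeEnvelope,
    config: StimulusConfig,
    rng: np.random.Generator | None = None,
) -> StimulusWaveform:
    """Synthesize the waveform for an amplitude envelope.

    Frozen policy: one snippet, derived deterministically from
    ``config.seed``, is reused for every syllable, so repeated calls give
    bit-identical waveforms.  Unfrozen policy: a fresh snippet per syllable
    is drawn from ``rng`` (successive calls on the same generator give
    different waveforms with the same envelope).
    """
    if not isinstance(envelope, AmplitudeEnvelope):
        envelope = AmplitudeEnvelope(tuple(envelope))
    if config.snippet_policy == "frozen":
        snippet = make_snippet(envelope.syllable_ms, config, _frozen_rng(config))
        syllables = [snippet] * len(envelope)
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        syllables = [
            make_snippet(envelope.syllable_ms, config, rng)
            for _ in range(len(envelope))
        ]
    gains = [lvl * config.base_gain for lvl in envelope.levels]
    prefilter = np.concatenate([g * s for g, s in zip(gains, syllables)])
    filtered = gaussian_smooth(prefilter, config.filter_sd_ms, config.sample_rate_hz)
    samples = normalize(filtered, config.norm_peak)
    return StimulusWaveform(
        samples=samples,
        sample_rate_hz=config.sample_rate_hz,
        envelope=envelope,
        policy_tag=config.snippet_policy,
        seed=config.seed,
        prefilter=prefilter,
    )


def envelope_transitions(envelope: AmplitudeEnvelope) -> list[int]:
    """Signed level changes between consecutive syllables (zeros dropped)."""
    diffs = np.diff(np.asarray(envelope.levels, dtype=int))
    return [int(d) for d in diffs if d != 0]


def envelope_epochs(
    envelope: AmplitudeEnvelope,
    small_levels: Iterable[int],
    large_levels: Iterable[int],
) -> list[tuple[str, float]]:
    """Maximal runs of small-/large-class syllables with their durations.

    ``small_levels`` and ``large_levels`` must jointly cover every level in
    the envelope. Returns ``(class, duration_ms)`` pairs in order, where
    class is ``"small"`` or ``"large"``.
    """
    small = set(int(v) for v in small_levels)
    large = set(int(v) for v in large_levels)
    if small & large:
        raise ValueError(f"small/large level sets overlap: {sorted(small & large)}")

    def classify(level: int) -> str:
        if level in small:
            return "small"
        if level in large:
            return "large"
        raise ValueError(f"level {level} is in neither the small nor the large set")

    epochs: list[tuple[str, float]] = []
    run_class, run_len = classify(envelope.levels[0]), 1
    for level in envelope.levels[1:]:
        cls = classify(level)
        if cls == run_class:
            run_len += 1
        else:
            epochs.append((run_class, run_len * envelope.syllable_ms))
            run_class, run_len = cls, 1
    epochs.append((run_class, run_len * envelope.syllable_ms))
    return epochs


def scramble_envelope(
    envelope: AmplitudeEnvelope, order: Sequence[int]
) -> AmplitudeEnvelope:
    """Permute syllables: output level i = input level ``order[i]``."""
    order = tuple(int(i) for i in order)
    if sorted(order) != list(range(len(envelope))):
        raise ValueError(
            f"order must be a permutation of 0..{len(envelope) - 1}, got {order}"
        )
    return replace(
        envelope, levels=tuple(envelope.levels[i] for i in order)
    )


def knockout_syllables(
    envelope: AmplitudeEnvelope,
    keep_mask: Sequence[bool],
    fill_level: int = 1,
) -> AmplitudeEnvelope:
    """Replace dropped syllables with ``fill_level``.

    Knocked-out positions are filled with low-amplitude noise rather than
    silence, so stimulation stays continuous throughout the sequence.
    """
    if len(keep_mask) != len(envelope):
        raise ValueError("keep_mask length must match envelope length")
    levels = tuple(
        lvl if keep else int(fill_level)
        for lvl, keep in zip(envelope.levels, keep_mask)
    )
    return replace(envelope, levels=levels)


def half_nogo_envelope(
    keep_mask: Sequence[bool] | None = None,
    fill_level: int = 1,
    order: Sequence[int] = FULL_NOGO_ORDER,
) -> AmplitudeEnvelope:
    """Shaping-stage distractor: scrambled GO with 4 of 8 syllables knocked out.

    The knocked-out positions are not pinned down by the task description;
    the default drops every other syllable (positions 1, 3, 5, 7) of the
    scrambled sequence and fills them with level-1 noise.
    """
    scrambled = scramble_envelope(GO_ENVELOPE, order)
    if keep_mask is None:
        keep_mask = [i % 2 == 0 for i in range(len(scrambled))]
    if sum(1 for k in keep_mask if not k) != len(scrambled) // 2:
        raise ValueError("half NO-GO knocks out exactly half of the syllables")
    return knockout_syllables(scrambled, keep_mask, fill_level)


def square_wave_stimulus(
    config: StimulusConfig,
    wave_hz: float = 10.0,
    duty: float = 0.5,
    noise_level: float = 1.0,
    duration_ms: float = 800.0,
    rng: np.random.Generator | None = None,
) -> StimulusWaveform:
    """Shaping-stage stimulus: a square wave riding on low-amplitude noise.

    The square wave alternates between +/- the level-4 amplitude; noise at
    ``noise_level`` (in envelope-level units, 0 for none) is added, then the
    result is filtered and normalised like every other stimulus.
    """
    if wave_hz <= 0:
        raise ValueError("wave_hz must be positive")
    if not 0 < duty < 1:
        raise ValueError("duty must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = n_samples(duration_ms, config.sample_rate_hz)
    t = np.arange(n) / config.sample_rate_hz
    phase = np.mod(t * wave_hz, 1.0)
    square = np.where(phase < duty, 1.0, -1.0)
    prefilter = 4.0 * config.base_gain * square
    if noise_level > 0:
        prefilter = prefilter + noise_level * config.base_gain * rng.standard_normal(n)
    filtered = gaussian_smooth(prefilter, config.filter_sd_ms, config.sample_rate_hz)
    samples = normalize(filtered, config.norm_peak)
    return StimulusWaveform(
        samples=samples,
        sample_rate_hz=config.sample_rate_hz,
        envelope=None,
        policy_tag="square_wave",
        seed=config.seed,
        prefilter=prefilter,
    )


def empirical_sd(waveform: StimulusWaveform | np.ndarray) -> float:
    """Sample standard deviation of the full waveform."""
    x = waveform.samples if isinstance(waveform, StimulusWaveform) else waveform
    return float(np.std(np.asarray(x, dtype=float), ddof=1))


def sd_matched(
    a: StimulusWaveform | np.ndarray,
    b: StimulusWaveform | np.ndarray,
    tol_fraction: float = 0.05,
) -> bool:
    """Whether two waveforms match in empirical SD to a relative tolerance."""
    sd_a, sd_b = empirical_sd(a), empirical_sd(b)
    return abs(sd_a - sd_b) / sd_b <= tol_fraction


def write_wav(waveform: StimulusWaveform, path) -> None:
    """Export as 32-bit float WAV at the waveform's sample rate."""
    wavfile.write(
        path, int(round(waveform.sample_rate_hz)), waveform.samples.astype(np.float32)
    )


def write_waveform_csv(waveform: StimulusWaveform, path) -> None:
    """Export as two-column CSV (time_s, value)."""
    t = np.arange(len(waveform.samples)) / waveform.sample_rate_hz
    np.savetxt(
        path,
        np.column_stack([t, waveform.samples]),
        delimiter=",",
        header="time_s,value",
        comments="",
    )


def parse_envelope(text: str, syllable_ms: float = 100.0) -> AmplitudeEnvelope:
    """Parse ``"3,1,4,2,3,1,4,2"`` (or JSON ``[3,1,...]``) into an envelope."""
    text = text.strip()
    if text.startswith("["):
        levels = json.loads(text)
    else:
        levels = [int(tok) for tok in text.replace(" ", "").split(",") if tok]
    return AmplitudeEnvelope(tuple(int(v) for v in levels), syllable_ms=syllable_ms)
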