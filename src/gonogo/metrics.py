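"""Performance statistics for GO/NO-GO sessions.

The measures implemented here:

* **Rebalanced percent correct** — percent correct computed as the
  equal-weight mean of hit rate and correct-rejection rate,
  ``100 x (0.5 x hit_rate + 0.5 x cr_rate)``.  Unlike the raw fraction of
  correct trials it is immune to unequal GO/NO-GO proportions: an agent
  that licks indiscriminately on 90% of trials scores 74% raw correct on a
  window with 40 GO / 10 NO-GO trials, but exactly 50% rebalanced.
* **Sliding-window performance** — either measure over a 50-trial moving
  window across the session.
* **Shuffle chance calibration** — the probability that a window reaches a
  performance threshold when stimulus identity is random with respect to
  the response, estimated by permuting stimulus labels against the fixed
  lick/no-lick response vector (10000 shuffles), preserving both the
  session's class counts and its overall lick rate.
* **d'** — z(hit rate) - z(false-alarm rate), with extreme rates clamped
  to [1/(2N), 1 - 1/(2N)] per class.
* **Discriminative lick latency** — the first 100 ms bin where the
  smoothed lick-rate difference between hit GO and correct-rejection NO-GO
  trials (best 50-trial window) exceeds a 95% null threshold built from 50
  random re-partitions of the same trials.  An upper bound on decision time.

Undefined quantities (a rebalanced window missing a class, a latency with
no threshold crossing) are reported as NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .task import GO, NOGO, SessionLog, TrialRecord

__all__ = [
    "PerformanceTrace",
    "CalibrationResult",
    "LickRateCurve",
    "LatencyResult",
    "percent_correct",
    "sliding_performance",
    "hit_fa_rates",
    "dprime",
    "shuffle_calibration",
    "simulate_chance_windows",
    "lick_rate_curve",
    "discriminative_lick_latency",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class PerformanceTrace:
    """Windowed percent-correct values along a session."""

    window_size: int
    centers: np.ndarray  # center trial index (1-based, may be half-integer)
    percent_correct: np.ndarray  # NaN where undefined
    rebalanced: bool


@dataclass
class CalibrationResult:
    """Chance probability of reaching a performance threshold."""

    threshold_pct: float
    n_shuffles: int
    p_estimate: float
    statistic: str = "per_window"


@dataclass
class LickRateCurve:
    """Trial-averaged, smoothed lick rate per time bin."""

    bin_ms: float
    times_ms: np.ndarray  # bin centers
    rate_hz: np.ndarray
    trial_class: str = "all"
    n_trials: int = 0


@dataclass
class LatencyResult:
    """Discriminative lick latency and the null machinery that produced it.

    ``latency_ms`` is the left edge of the first bin where the true
    GO-minus-NO-GO rate difference exceeds ``null_threshold`` (NaN when the
    curve never crosses or the preconditions fail; see ``diagnostic``).
    """

    latency_ms: float
    times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    diff_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_threshold: float | np.ndarray = np.nan
    n_repeats: int = 0
    window: tuple[int, int] | None = None
    diagnostic: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.latency_ms)


# ---------------------------------------------------------------------------
# percent correct


def _counts(trials: Sequence[TrialRecord]) -> tuple[int, int, int, int]:
    n_go = sum(1 for t in trials if t.stimulus_class == GO)
    n_nogo = len(trials) - n_go
    hits = sum(1 for t in trials if t.outcome == "hit")
    crs = sum(1 for t in trials if t.outcome == "correct_rejection")
    return n_go, n_nogo, hits, crs


def percent_correct(trials: Sequence[TrialRecord], rebalanced: bool = False) -> float:
    """Percent correct of a set of trials, raw or rebalanced.

    Raw: ``100 x (hits + correct rejections) / n``.  Rebalanced:
    ``100 x (0.5 x hit_rate + 0.5 x cr_rate)``; NaN if either class is
    absent (the equal-weight mean is undefined).
    """
    if len(trials) == 0:
        raise ValueError("percent_correct of an empty trial set is undefined")
    n_go, n_nogo, hits, crs = _counts(trials)
    if rebalanced:
        if n_go == 0 or n_nogo == 0:
            return float("nan")
        return 100.0 * (0.5 * hits / n_go + 0.5 * crs / n_nogo)
    return 100.0 * (hits + crs) / len(trials)


def _session_vectors(session: SessionLog) -> tuple[np.ndarray, np.ndarray]:
    """(is_go, licked) boolean vectors for a session."""
    is_go = np.array([t.stimulus_class == GO for t in session.trials])
    licked = np.array([t.licked for t in session.trials])
    return is_go, licked


def _windowed_rebalanced(
    is_go: np.ndarray, licked: np.ndarray, window_size: int
) -> np.ndarray:
    """Rebalanced percent correct of every contiguous window (NaN where a
    class is missing).  Works on (..., n_trials) stacked boolean arrays."""
    go = is_go.astype(float)
    hit = (is_go & licked).astype(float)
    cr = (~is_go & ~licked).astype(float)

    def winsum(x: np.ndarray) -> np.ndarray:
        c = np.cumsum(x, axis=-1)
        c = np.concatenate([np.zeros_like(c[..., :1]), c], axis=-1)
        return c[..., window_size:] - c[..., :-window_size]

    n_go = winsum(go)
    n_nogo = window_size - n_go
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 100.0 * (
            0.5 * winsum(hit) / n_go + 0.5 * winsum(cr) / n_nogo
        )
    vals[(n_go == 0) | (n_nogo == 0)] = np.nan
    return vals


def sliding_performance(
    session: SessionLog, window_size: int = 50, rebalanced: bool = True
) -> PerformanceTrace:
    """Percent correct over a sliding window of trials (step 1)."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = len(session.trials)
    if n < window_size:
        raise ValueError(
            f"session has {n} trials, fewer than window_size={window_size}"
        )
    is_go, licked = _session_vectors(session)
    if rebalanced:
        vals = _windowed_rebalanced(is_go, licked, window_size)
    else:
        correct = (is_go & licked) | (~is_go & ~licked)
        c = np.concatenate([[0], np.cumsum(correct)])
        vals = 100.0 * (c[window_size:] - c[:-window_size]) / window_size
    starts = np.arange(1, n - window_size + 2)
    centers = starts + (window_size - 1) / 2.0
    return PerformanceTrace(
        window_size=window_size,
        centers=centers,
        percent_correct=vals,
        rebalanced=rebalanced,
    )


# ---------------------------------------------------------------------------
# signal-detection measures


def hit_fa_rates(session: SessionLog | Sequence[TrialRecord]) -> tuple[float, float]:
    """(hit rate, false-alarm rate) of a session."""
    trials = session.trials if isinstance(session, SessionLog) else session
    n_go, n_nogo, hits, crs = _counts(trials)
    if n_go == 0 or n_nogo == 0:
        raise ValueError("hit/FA rates need at least one trial of each class")
    return hits / n_go, (n_nogo - crs) / n_nogo


def dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Sensitivity d' = z(hit) - z(FA) with extreme-rate clamping.

    Rates are clamped to [1/(2N), 1 - 1/(2N)] for the class's trial count N
    so that perfect or null rates give a finite value.
    """
    if n_go < 1 or n_nogo < 1:
        raise ValueError("d' needs at least one trial of each class")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_go), 1.0 - 1.0 / (2 * n_go)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_nogo), 1.0 - 1.0 / (2 * n_nogo)))
    return float(norm.ppf(h) - norm.ppf(f))


# ---------------------------------------------------------------------------
# shuffle chance calibration


def shuffle_calibration(
    session: SessionLog,
    threshold_pct: float = 75.0,
    window_size: int = 50,
    n_shuffles: int = 10000,
    rng: np.random.Generator | int | None = None,
    statistic: str = "per_window",
) -> CalibrationResult:
    """Chance probability of reaching ``threshold_pct`` rebalanced correct.

    Each shuffle permutes the session's stimulus-label vector against the
    fixed lick/no-lick response vector (preserving both the class counts
    and the lick count), recomputes the rebalanced sliding-window
    performance, and records threshold exceedance.  With
    ``statistic="per_window"`` the estimate is the fraction of
    (shuffle, window) values at or above threshold; with ``"best_window"``
    it is the fraction of shuffles whose best window reaches it.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if statistic not in ("per_window", "best_window"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(rng)
    is_go, licked = _session_vectors(session)
    n = len(is_go)
    if not (is_go.any() and (~is_go).any()):
        raise ValueError("calibration needs both trial classes in the session")
    if n < window_size:
        raise ValueError("session shorter than window_size")

    # permute labels in batches to bound memory at ~batch x n
    batch = max(1, int(2_000_000 // max(n, 1)))
    exceed = 0
    total = 0
    done = 0
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        shuffled_go = is_go[perms]
        vals = _windowed_rebalanced(shuffled_go, licked[None, :], window_size)
        if statistic == "per_window":
            exceed += int(np.nansum(vals >= threshold_pct))
            total += int(np.isfinite(vals).sum())
        else:
            best = np.nanmax(vals, axis=-1)
            exceed += int(np.sum(best >= threshold_pct))
            total += b
        done += b
    p = exceed / total if total else float("nan")
    return CalibrationResult(
        threshold_pct=float(threshold_pct),
        n_shuffles=n_shuffles,
        p_estimate=float(p),
        statistic=statistic,
    )


def simulate_chance_windows(
    n_windows: int,
    n_go: int = 25,
    n_nogo: int = 25,
    lick_prob: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Rebalanced percent correct of windows with stimulus-independent licking.

    Each window holds ``n_go`` GO and ``n_nogo`` NO-GO trials whose
    responses are i.i.d. Bernoulli(``lick_prob``) regardless of class —
    the null model behind chance calibration.  Since trials are exchange-
    able, per-window hit and false-alarm counts are binomial, which lets
    millions of windows be simulated directly.
    """
    if n_windows < 1 or n_go < 1 or n_nogo < 1:
        raise ValueError("n_windows, n_go and n_nogo must be >= 1")
    rng = np.random.default_rng(rng)
    hits = rng.binomial(n_go, lick_prob, size=n_windows)
    fas = rng.binomial(n_nogo, lick_prob, size=n_windows)
    return 100.0 * (0.5 * hits / n_go + 0.5 * (n_nogo - fas) / n_nogo)


# ---------------------------------------------------------------------------
# lick-rate curves and discriminative lick latency


def _bin_edges(bin_ms: float, t_max_ms: float) -> np.ndarray:
    n_bins = int(np.ceil(t_max_ms / bin_ms))
    return np.arange(n_bins + 1) * bin_ms


def _binned_rates(
    trials: Sequence[TrialRecord], edges: np.ndarray, bin_ms: float
) -> np.ndarray:
    """(n_trials, n_bins) lick rate matrix in Hz."""
    rates = np.zeros((len(trials), len(edges) - 1))
    for i, t in enumerate(trials):
        counts, _ = np.histogram(np.asarray(t.lick_times_ms), bins=edges)
        rates[i] = counts / (bin_ms / 1000.0)
    return rates


def _smooth_bins(curve: np.ndarray, smoothing_sd_ms: float, bin_ms: float) -> np.ndarray:
    if smoothing_sd_ms <= 0:
        return curve
    return gaussian_filter1d(
        curve, smoothing_sd_ms / bin_ms, axis=-1, mode="reflect", truncate=4.0
    )


def lick_rate_curve(
    trials: Sequence[TrialRecord],
    bin_ms: float = 100.0,
    smoothing_sd_ms: float = 50.0,
    t_max_ms: float = 2300.0,
    trial_class: str = "all",
) -> LickRateCurve:
    """Trial-averaged lick rate versus time, Gaussian-smoothed along time."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    edges = _bin_edges(bin_ms, t_max_ms)
    if len(trials) == 0:
        mean = np.zeros(len(edges) - 1)
    else:
        mean = _binned_rates(trials, edges, bin_ms).mean(axis=0)
    mean = _smooth_bins(mean, smoothing_sd_ms, bin_ms)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LickRateCurve(
        bin_ms=bin_ms,
        times_ms=centers,
        rate_hz=mean,
        trial_class=trial_class,
        n_trials=len(trials),
    )


def discriminative_lick_latency(
    session: SessionLog,
    window_size: int = 50,
    n_repeats: int = 50,
    alpha: float = 0.05,
    bin_ms: float = 100.0,
    smoothing_sd_ms: float = 50.0,
    rng: np.random.Generator | int | None = None,
    threshold_mode: str = "pooled",
) -> LatencyResult:
    """First time the GO/NO-GO lick-rate difference beats a resampled null.

    Procedure: (1) pick the best ``window_size``-trial window by rebalanced
    performance; (2) within it, compute the smoothed lick-rate curves of
    hit GO and correct-rejection NO-GO trials and their difference;
    (3) build ``n_repeats`` fake GO/NO-GO splits by randomly re-partitioning
    the pooled trials, preserving group sizes; (4) set the null threshold
    to the (1 - alpha) quantile of the fake difference-curve values —
    pooled over all time bins by default, per bin with
    ``threshold_mode="per_bin"``; (5) the latency is the left edge of the
    first bin whose true difference exceeds the threshold.

    Precondition failures (no hit GO or no correct-rejection NO-GO trial in
    the best window) yield a NaN latency with a diagnostic, not an error.
    """
    if threshold_mode not in ("pooled", "per_bin"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(rng)

    n = len(session.trials)
    if n == 0:
        return LatencyResult(latency_ms=float("nan"), diagnostic="empty session")
    window_size = min(window_size, n)
    trace = sliding_performance(session, window_size, rebalanced=True)
    if np.all(np.isnan(trace.percent_correct)):
        return LatencyResult(
            latency_ms=float("nan"),
            diagnostic="no window contains both trial classes",
        )
    best = int(np.nanargmax(trace.percent_correct))
    window_trials = session.trials[best : best + window_size]

    hit_trials = [t for t in window_trials if t.outcome == "hit"]
    cr_trials = [t for t in window_trials if t.outcome == "correct_rejection"]
    if not hit_trials or not cr_trials:
        return LatencyResult(
            latency_ms=float("nan"),
            window=(best + 1, best + window_size),
            diagnostic=(
                f"best window has {len(hit_trials)} hit and "
                f"{len(cr_trials)} correct-rejection trials; both required"
            ),
        )

    t_max_ms = session.config.trial_duration_ms
    edges = _bin_edges(bin_ms, t_max_ms)
    centers = (edges[:-1] + edges[1:]) / 2.0
    rates = _binned_rates(hit_trials + cr_trials, edges, bin_ms)
    n_hit = len(hit_trials)

    def diff_curve(rows_go: np.ndarray, rows_nogo: np.ndarray) -> np.ndarray:
        go = _smooth_bins(rates[rows_go].mean(axis=0), smoothing_sd_ms, bin_ms)
        ng = _smooth_bins(rates[rows_nogo].mean(axis=0), smoothing_sd_ms, bin_ms)
        return go - ng

    idx = np.arange(len(rates))
    true_diff = diff_curve(idx[:n_hit], idx[n_hit:])

    fakes = np.empty((n_repeats, len(centers)))
    for r in range(n_repeats):
        perm = rng.permutation(len(rates))
        fakes[r] = diff_curve(perm[:n_hit], perm[n_hit:])

    if threshold_mode == "pooled":
        threshold: float | np.ndarray = float(np.quantile(fakes, 1.0 - alpha))
    else:
        threshold = np.quantile(fakes, 1.0 - alpha, axis=0)

    above = true_diff > threshold
    if not np.any(above):
        latency = float("nan")
        diagnostic = "difference curve never exceeds the null threshold"
    else:
        latency = float(edges[:-1][int(np.argmax(above))])
        diagnostic = ""
    return LatencyResult(
        latency_ms=latency,
        times_ms=centers,
        diff_curve=true_diff,
        null_threshold=threshold,
        n_repeats=n_repeats,
        window=(best + 1, best + window_size),
        diagnostic=diagnostic,
    )
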