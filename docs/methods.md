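# Methods

This note documents the models, parameters and numerical choices behind
the toolkit, and what its synthetic-data tests do and do not establish
about real behavioral data.

## Stimulus model

A stimulus is defined by an **amplitude envelope**: an ordered list of
integer levels (1–4), one per 100 ms syllable. Synthesis follows the
construction order: draw a 100 ms white-noise snippet, stitch one snippet
per syllable into a chain, multiply samplewise by the piecewise-constant
envelope, convolve with a Gaussian, peak-normalise.

Choices where the construction leaves freedom:

* **Noise distribution** — zero-mean Gaussian with unit SD before gain.
  Only second-order statistics matter downstream (empirical SD matching,
  energy conservation), so any white process would do; Gaussian is the
  standard choice for filtered-noise vibrotactile stimuli.
* **Level→amplitude mapping** — linear: syllable gain = level ×
  `base_gain`. The arithmetic done on levels elsewhere (transition
  magnitudes of −3/+3 between levels 4 and 1) presumes a linear scale.
  Whether physical actuator deflection is linear in drive level is a
  hardware question outside the model; the toolkit works in normalised
  drive units throughout (`norm_peak`, default 1.0).
* **Sample counts** — per-syllable round-half-away-from-zero of
  duration × rate (100 ms at 12207 Hz → 1221 samples); the concatenation
  defines total length (8 × 1221 = 9768 samples ≈ 800.2 ms). Duration
  invariants therefore hold to within one sample period per syllable.
* **Filtering** — applied to the full envelope-multiplied chain (not per
  syllable), Gaussian kernel SD 1.64 ms truncated at ±4 SD, unit-sum,
  reflective edge handling to avoid onset artifacts.
* **Frozen vs unfrozen** — frozen reuses a single snippet for every
  syllable and every call, derived deterministically from
  (`seed`, a fixed internal tag); unfrozen draws a fresh snippet per
  syllable from the caller's generator, so successive calls differ while
  keeping the same envelope. SD matching between frozen and unfrozen
  variants uses a 5% relative tolerance by default.
* **Knockouts** — the shaping-stage "half" NO-GO scrambles the GO
  envelope (default: the same permutation that produces the full NO-GO)
  and replaces 4 of 8 syllables with level-1 noise rather than silence,
  keeping stimulation continuous so no silent gap can be mistaken for the
  end of the sequence. Which positions were dropped is not determined by
  the task description; the default drops alternating positions and both
  the mask and the fill level are configurable.
* **Square wave** — the easy shaping distractor defaults to 10 Hz, 50%
  duty, level-4 amplitude riding on level-1 noise; it only needs to be
  clearly different from the GO sequence, and all parameters are exposed.

## Trial engine

Timing defaults: 0.8 s stimulation, 1.5 s response period, 2–5 s uniform
extra delay after a false alarm. The outcome is determined solely by the
presence of a lick inside the response window; licks during stimulation
are recorded (they occur in real rasters) but neither abort nor decide the
trial, since no early-lick punishment is part of the task. The response
window is closed on both ends, `[stimulation end, stimulation end +
response]`: a lick exactly at stimulus offset counts as a response. The
boundary must be fixed somewhere; for jittered continuous lick times the
choice has measure zero. GO/NO-GO assignment is i.i.d.
Bernoulli(`go_fraction`) by default, with an explicit schedule available,
because real training routinely varies the GO proportion — which is
precisely what motivates the rebalanced measure. The baseline inter-trial
interval has no canonical value and is config metadata only.

## Agents

Lick trains are regular at `lick_rate_hz` (default 7 Hz, typical rodent
licking) with optional Gaussian per-lick jitter; every analysis consumes
binned rates, which are insensitive to fine train structure. The
transition detector reads envelope levels instantaneously and noiselessly
— an ideal-observer abstraction, not an acoustic front end — and on GO
trials begins sustained licking at `divergence + decision_latency_ms`,
where the divergence is the first syllable at which the GO and NO-GO
envelopes differ (100 ms for GO vs full NO-GO). Real animals may use
later evidence on poor sessions; the latency is deliberately a free
parameter rather than a mechanistic claim.

## Metrics

* **Rebalanced percent correct** `= 100·(½·hit rate + ½·CR rate)`.
  Windows lacking a class carry NaN, never a silent 0.
* **Shuffle calibration** permutes the stimulus-label vector against the
  fixed response vector, preserving both margins (class counts and lick
  count) — the natural exchangeable null for "no relationship between
  stimulus and response". The reported p is per-window (the fraction of
  shuffle × window values reaching threshold); a best-window variant is
  available via `statistic="best_window"`. For a single 50-trial window
  the two coincide.
* **d′** clamps rates to [1/2N, 1 − 1/2N] per class before the inverse
  normal transform — the standard correction for perfect or null rates.
* **Discriminative lick latency** uses hit-GO minus CR-NO-GO smoothed
  lick-rate curves (100 ms bins, Gaussian smoothing SD 50 ms — smoothing
  is part of the published procedure but its parameter is not; 50 ms on
  100 ms bins smooths without displacing onsets by more than a bin) within
  the best 50-trial window. The null threshold is the 95th percentile of
  difference-curve values from 50 random re-partitions of the pooled
  trials preserving group sizes, pooled over all time bins by default
  (the published threshold is a single flat line); a per-bin variant is
  available. The latency is the left edge of the first bin exceeding the
  threshold; no crossing, or a best window without both hit and CR trials,
  yields NaN with a diagnostic string.

## Synthetic data: what passing tests show

The generator emulates 200–300-trial head-fixed sessions with
configurable GO fraction, agents whose GO/NO-GO lick rates diverge at a
parameterized latency, and purely random lickers for null calibration. It
reproduces the *statistical structure* the analyses rely on — binomial
outcome counts, Poisson-like binned lick rates, exchangeability under the
null — but not learning dynamics within or across sessions, motivational
drift, or sensory noise in evidence extraction. Passing the latency
recovery test therefore shows the estimator is unbiased to within one bin
for agents with a sharp, stationary decision time; real sessions with
drifting latencies are summarised, not recovered, by the same number.
Animal- and human-level performance values (median percent correct,
frozen/unfrozen hit rates, performance–latency correlations) depend on
the original subjects and are out of scope; the suite instead verifies
the invariants that make such numbers comparable across sessions, e.g.
that the rebalanced measure is independent of GO fraction.

## Problem sizes and determinism

Chance calibration is validated on 10⁶ simulated balanced 50-trial
windows with lick probability 0.5 — the worst case for response variance,
hence a conservative bound for any session-specific lick rate; because
null responses are i.i.d. Bernoulli, window hit/FA counts are binomial
and are drawn directly, which is exact, not an approximation. Latency
recovery uses 100 independently seeded 250-trial sessions per latency
value (0, 100, 300 ms) with the full 50-repeat resampling per session.
All stochastic stages take an explicit seed or generator; the pipeline
derives per-stage sub-seeds from the run seed, so a (config, seed) pair
reproduces session logs and report JSON byte for byte.

## Known limitations

* The legacy `.mat` trial-matrix importer maps a deposited rectangular
  layout by convention (class, lick flag, lick-time columns) and is
  untested against real deposits.
* The frozen/unfrozen comparison matches waveform SDs but the toolkit
  does not model receptor or whisker mechanics, so "same SD" does not
  imply "same percept".
* Shuffle calibration assumes trial exchangeability; serial dependence
  (e.g. post-false-alarm timeouts altering motivation) is not modeled.
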