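"""Performance statistics: percent correct, d', calibration, latency."""

import numpy as np
import pytest
from scipy.stats import norm

from gonogo import (
    GO,
    NOGO,
    FULL_NOGO_ENVELOPE,
    GO_ENVELOPE,
    ParametricAgent,
    RandomLicker,
    TaskConfig,
    TransitionDetector,
    TrialRecord,
    discriminative_lick_latency,
    dprime,
    hit_fa_rates,
    lick_rate_curve,
    percent_correct,
    run_session,
    shuffle_calibration,
    simulate_chance_windows,
    sliding_performance,
)
from conftest import make_window


class TestPercentCorrect:
    def test_unbalanced_worked_example(self):
        """40 GO / 10 NO-GO at 90% hit and 90% FA rates -> 74% raw correct."""
        trials = make_window(n_go=40, n_nogo=10, n_hits=36, n_crs=1)
        assert percent_correct(trials) == pytest.approx(74.0)

    def test_rebalanced_worked_example(self):
        """The same indiscriminate licker scores exactly 50% rebalanced."""
        trials = make_window(n_go=40, n_nogo=10, n_hits=36, n_crs=1)
        assert percent_correct(trials, rebalanced=True) == pytest.approx(50.0)

    def test_all_correct_both_measures(self):
        trials = make_window(n_go=25, n_nogo=25, n_hits=25, n_crs=25)
        assert percent_correct(trials) == 100.0
        assert percent_correct(trials, rebalanced=True) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percent_correct([])

    def test_rebalanced_single_class_undefined(self):
        trials = make_window(n_go=10, n_nogo=0, n_hits=5, n_crs=0)
        assert np.isnan(percent_correct(trials, rebalanced=True))

    def test_brute_force_oracle_equivalence(self):
        """Vectorised measures match naive per-trial recomputation."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            trials = []
            n_go = n_nogo = hits = crs = 0
            for i in range(n):
                is_go = rng.random() < 0.5 or i == 0  # ensure >=1 GO
                licked = rng.random() < 0.5 or i == 1
                if is_go:
                    n_go += 1
                    hits += licked
                    outcome = "hit" if licked else "miss"
                else:
                    n_nogo += 1
                    crs += not licked
                    outcome = "false_alarm" if licked else "correct_rejection"
                trials.append(
                    TrialRecord(
                        index=i + 1,
                        stimulus_class=GO if is_go else NOGO,
                        stimulus_id="x",
                        lick_times_ms=(900.0,) if licked else (),
                        outcome=outcome,
                        rewarded=(outcome == "hit"),
                    )
                )
            assert percent_correct(trials) == pytest.approx(100 * (hits + crs) / n)
            if n_go and n_nogo:
                expected = 100 * (0.5 * hits / n_go + 0.5 * crs / n_nogo)
                assert percent_correct(trials, rebalanced=True) == pytest.approx(
                    expected
                )
                h, f = hit_fa_rates(trials)
                assert h == pytest.approx(hits / n_go)
                assert f == pytest.approx(1 - crs / n_nogo)


class TestSlidingPerformance:
    def test_perfect_agent(self):
        log = run_session(ParametricAgent(1.0, 0.0), TaskConfig(n_trials=100, seed=0))
        trace = sliding_performance(log, 50)
        assert len(trace.percent_correct) == 51
        np.testing.assert_allclose(trace.percent_correct, 100.0)

    def test_indiscriminate_licker_exactly_50(self):
        cfg = TaskConfig(n_trials=100, seed=0)
        log = run_session(RandomLicker(1.0), cfg, schedule=[GO, NOGO] * 50)
        trace = sliding_performance(log, 50, rebalanced=True)
        np.testing.assert_array_equal(trace.percent_correct, 50.0)

    def test_best_window_at_least_session_mean(self, transition_session):
        trace = sliding_performance(transition_session, 50)
        overall = percent_correct(transition_session.trials, rebalanced=True)
        assert np.nanmax(trace.percent_correct) >= overall - 1e-9

    def test_undefined_windows_marked(self):
        cfg = TaskConfig(n_trials=30, seed=0)
        log = run_session(RandomLicker(0.5), cfg, schedule=[GO] * 20 + [NOGO] * 10)
        trace = sliding_performance(log, 10, rebalanced=True)
        assert np.isnan(trace.percent_correct[0])  # all-GO window
        assert np.isnan(trace.percent_correct[-1])  # all-NOGO window
        assert np.isfinite(trace.percent_correct[14])  # mixed window

    def test_window_larger_than_session_rejected(self, random_session):
        with pytest.raises(ValueError, match="window"):
            sliding_performance(random_session, 1000)


class TestDprime:
    @pytest.mark.parametrize("rate", [0.9, 0.5])
    def test_equal_rates_zero(self, rate):
        assert dprime(rate, rate, 1000, 1000) == pytest.approx(0.0)

    def test_unit_z_example(self):
        # z(0.8413) = +1 and z(0.1587) = -1
        assert dprime(norm.cdf(1), norm.cdf(-1), 10**6, 10**6) == pytest.approx(
            2.0, abs=1e-3
        )

    def test_extreme_rates_clamped_finite(self):
        d = dprime(1.0, 0.0, 25, 25)
        assert np.isfinite(d)
        assert d == pytest.approx(2 * norm.ppf(1 - 1 / 50), abs=1e-9)

    def test_zero_class_rejected(self):
        with pytest.raises(ValueError):
            dprime(0.9, 0.1, 0, 10)
        with pytest.raises(ValueError):
            hit_fa_rates(make_window(10, 0, 5, 0))


class TestShuffleCalibration:
    def test_degenerate_all_lick_gives_zero(self):
        cfg = TaskConfig(n_trials=50, seed=0)
        log = run_session(RandomLicker(1.0), cfg, schedule=[GO, NOGO] * 25)
        res = shuffle_calibration(log, 75.0, 50, n_shuffles=200, rng=0)
        assert res.p_estimate == 0.0

    def test_monotone_in_threshold(self, random_session):
        p75 = shuffle_calibration(random_session, 75.0, 50, 2000, rng=1).p_estimate
        p70 = shuffle_calibration(random_session, 70.0, 50, 2000, rng=1).p_estimate
        assert p75 <= p70

    def test_best_window_geq_per_window(self, random_session):
        per = shuffle_calibration(
            random_session, 70.0, 50, 1000, rng=2, statistic="per_window"
        ).p_estimate
        best = shuffle_calibration(
            random_session, 70.0, 50, 1000, rng=2, statistic="best_window"
        ).p_estimate
        assert best >= per

    def test_shuffle_preserves_margins(self):
        """p is estimated under fixed lick count and class counts; a session
        whose licks exactly separate classes still shows chance-level
        shuffled performance."""
        cfg = TaskConfig(n_trials=50, seed=0)
        log = run_session(ParametricAgent(1.0, 0.0), cfg, schedule=[GO, NOGO] * 25)
        res = shuffle_calibration(log, 99.9, 50, n_shuffles=2000, rng=3)
        assert res.p_estimate < 0.01  # the true labeling is exceptional

    def test_invalid_args(self, random_session):
        with pytest.raises(ValueError):
            shuffle_calibration(random_session, 75.0, 50, 0)
        with pytest.raises(ValueError):
            shuffle_calibration(random_session, 75.0, 50, 10, statistic="median")

    def test_chance_simulation_matches_trialwise_formula(self):
        """The vectorised null simulation equals percent_correct on
        explicitly constructed windows with the same hit/CR counts."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            hits = int(rng.integers(0, 26))
            fas = int(rng.integers(0, 26))
            trials = make_window(25, 25, hits, 25 - fas)
            expected = percent_correct(trials, rebalanced=True)
            assert 100.0 * (0.5 * hits / 25 + 0.5 * (25 - fas) / 25) == pytest.approx(
                expected
            )
        vals = simulate_chance_windows(2000, 25, 25, 0.5, rng=6)
        assert vals.min() >= 0.0 and vals.max() <= 100.0
        assert vals.mean() == pytest.approx(50.0, abs=1.0)


class TestLickRateCurve:
    def test_no_licks_zero_curve(self):
        trials = make_window(5, 5, 0, 5)
        curve = lick_rate_curve(trials, smoothing_sd_ms=0.0)
        miss_trials = [t for t in trials if t.outcome == "miss"]
        np.testing.assert_array_equal(
            lick_rate_curve(miss_trials, smoothing_sd_ms=0.0).rate_hz, 0.0
        )

    def test_single_lick_bin_rate(self):
        trials = make_window(4, 0, 4, 0)  # one lick at 900 ms per trial
        curve = lick_rate_curve(trials, bin_ms=100.0, smoothing_sd_ms=0.0)
        assert curve.rate_hz[9] == pytest.approx(10.0)  # 1 lick / 0.1 s
        assert np.sum(curve.rate_hz != 0) == 1

    def test_smoothing_preserves_rate_mass(self):
        trials = make_window(4, 0, 4, 0)
        raw = lick_rate_curve(trials, smoothing_sd_ms=0.0)
        smooth = lick_rate_curve(trials, smoothing_sd_ms=50.0)
        assert smooth.rate_hz.sum() == pytest.approx(raw.rate_hz.sum())


class TestDiscriminativeLickLatency:
    def test_recovers_divergence_plus_latency(self):
        agent = TransitionDetector(
            GO_ENVELOPE, FULL_NOGO_ENVELOPE, decision_latency_ms=100.0, fa_rate=0.1
        )
        log = run_session(agent, TaskConfig(n_trials=250, seed=8))
        res = discriminative_lick_latency(log, rng=8)
        assert abs(res.latency_ms - 200.0) <= 100.0

    def test_indiscriminate_licking_undefined(self):
        cfg = TaskConfig(n_trials=100, seed=0)
        log = run_session(RandomLicker(0.5, jitter_ms=0.0), cfg)
        res = discriminative_lick_latency(log, rng=0)
        # hit and CR trials have identical lick statistics: no real crossing,
        # or at best a spurious one - never before the response window opens
        if res.defined:
            assert res.latency_ms >= 700.0

    def test_latency_not_before_first_go_lick(self, transition_session):
        res = discriminative_lick_latency(transition_session, rng=1)
        first_lick = min(
            t.lick_times_ms[0]
            for t in transition_session.trials
            if t.outcome == "hit" and t.lick_times_ms
        )
        assert res.defined
        assert res.latency_ms >= first_lick - 100.0  # within bin resolution

    def test_missing_class_gives_diagnostic(self):
        cfg = TaskConfig(n_trials=60, seed=0)
        log = run_session(RandomLicker(1.0), cfg)  # no correct rejections
        res = discriminative_lick_latency(log, rng=0)
        assert not res.defined
        assert "correct-rejection" in res.diagnostic or "class" in res.diagnostic

    def test_per_bin_mode_runs(self, transition_session):
        res = discriminative_lick_latency(
            transition_session, rng=2, threshold_mode="per_bin"
        )
        assert res.defined
        assert np.asarray(res.null_threshold).shape == res.times_ms.shape


class TestRebalancedInvariance:
    def test_go_fraction_invariance(self):
        """For fixed hit/CR rates the rebalanced measure is unaffected by
        the GO fraction, while the raw measure moves with it."""
        results = {}
        for frac in (0.5, 0.8):
            cfg = TaskConfig(n_trials=20_000, go_fraction=frac, seed=13)
            log = run_session(RandomLicker(0.9), cfg)
            results[frac] = (
                percent_correct(log.trials, rebalanced=True),
                percent_correct(log.trials),
            )
        assert results[0.5][0] == pytest.approx(results[0.8][0], abs=1.0)
        assert results[0.5][0] == pytest.approx(50.0, abs=1.0)
        # raw measure rises toward the hit rate as GO trials dominate
        assert results[0.8][1] > results[0.5][1] + 15.0
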