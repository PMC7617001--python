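"""MEP measurement, RMT staircase, IO fitting and statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from pwmtms.analysis import (
    StaircaseError,
    blocks_from_trials,
    cohens_d,
    detect_latency,
    determine_rmt,
    fit_io_curve,
    latency_by_amplitude,
    measure_peak_to_peak,
    rm_anova_two_level,
    run_staircase,
)
from pwmtms.study import CohortConfig, EMGTrace, generate_cohort, simulate_trial

FS = 5000.0
N_PRE = 500  # 100 ms at 5 kHz


def _trace(post, pre=None):
    pre = np.zeros(N_PRE) if pre is None else pre
    return EMGTrace(FS, np.r_[pre, post], N_PRE)


class TestMeasurePeakToPeak:
    def test_sine_gives_twice_amplitude(self):
        t = np.arange(500) / FS * 1e3
        post = 100.0 * np.sin(2 * np.pi * t / 10.0)
        m = measure_peak_to_peak(_trace(post))
        assert m.peak_to_peak == pytest.approx(200.0, rel=1e-2)
        assert not m.floored

    def test_flat_trace_floored_to_twenty(self):
        m = measure_peak_to_peak(_trace(np.zeros(500)))
        assert m.peak_to_peak == 20.0
        assert m.floored

    def test_generator_roundtrip_of_known_amplitude(self):
        cfg = CohortConfig(emg_noise_sd=0.0, trial_log_sd=0.0, seed=1)
        p = generate_cohort(cfg)[0]
        rng = np.random.default_rng(0)
        tr = simulate_trial(p, "magstim", p.io_midpoint["magstim"] + 15.0, rng)
        expected = 10.0 ** p.io_value("magstim", p.io_midpoint["magstim"] + 15.0)
        # the wavelet crest can fall between samples (random latency), which
        # shaves at most ~0.3 % off the sampled peak-to-peak
        assert measure_peak_to_peak(tr.trace).peak_to_peak == pytest.approx(
            expected, rel=5e-3
        )

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            measure_peak_to_peak(_trace(np.zeros(100)), window_ms=(15.0, 45.0))


class TestDetectLatency:
    def test_step_onset_recovered(self):
        post = np.zeros(500)
        k = int(22.0 * FS / 1e3)
        post[k:] = 100.0
        lat, ok = detect_latency(_trace(post))
        assert ok
        assert lat == pytest.approx(22.0, abs=1e3 / FS)

    def test_known_onset_detected_within_one_ms(self, rng):
        """1 mV MEPs over 5 µV noise: onset recovered within 1 ms in >= 95 %
        of draws."""
        cfg = CohortConfig(seed=3, latency_sd=0.0)
        p = generate_cohort(cfg)[0]
        good = 0
        n = 1000
        for _ in range(n):
            tr = simulate_trial(p, "magstim", p.io_midpoint["magstim"] + 20.0, rng)
            lat, ok = detect_latency(tr.trace)
            if ok and abs(lat - p.latency) <= 1.0:
                good += 1
        assert good >= 0.95 * n

    def test_noise_only_rarely_detected(self, rng):
        n, hits = 1000, 0
        for _ in range(n):
            tr = _trace(rng.normal(0, 5.0, 500), rng.normal(0, 5.0, N_PRE))
            _, ok = detect_latency(tr)
            hits += ok
        assert hits <= 0.05 * n

    def test_latency_never_in_prestimulus_window(self, rng):
        for _ in range(50):
            tr = _trace(rng.normal(0, 5.0, 500), rng.normal(0, 5.0, N_PRE))
            lat, ok = detect_latency(tr, min_duration_ms=0.0)
            if ok:
                assert lat >= 0.0

    def test_missing_baseline_rejected(self):
        # the trace type itself enforces the exact 100 ms pre-stimulus window
        with pytest.raises(ValueError):
            EMGTrace(FS, np.zeros(600), 100)


class TestStaircase:
    def test_hard_threshold_participant(self):
        """Deterministic success iff intensity >= 40, starting at 45."""

        def runner(x):
            return 10 if x >= 40.0 else 0

        rmt, history = run_staircase(runner, 45.0)
        assert rmt == 40.0
        assert [h[0] for h in history] == [45, 44, 43, 42, 41, 40, 39]

    def test_replay_matches_live_staircase(self):
        def runner(x):
            return 10 if x >= 40.0 else 0

        _, history = run_staircase(runner, 45.0)
        est = determine_rmt(history, participant=1, device="magstim")
        assert est.rmt == 40.0
        assert est.successes[-1] < 5

    def test_estimate_matches_exact_binomial_enumeration(self):
        """Toy participant: success probability 0 below 41, 0.5 at 41, 1 at
        42. Exact enumeration gives P(RMT=41) = P(Bin(10, .5) >= 5) = 0.6230,
        else RMT = 42; 500 seeded runs must match, with mode 41."""
        p_block_41 = float(sps.binom.sf(4, 10, 0.5))  # P(>=5 of 10)
        rng = np.random.default_rng(2024)

        def make_runner():
            def runner(x):
                p = {40.0: 0.0, 41.0: 0.5, 42.0: 1.0}[x]
                return int(rng.binomial(10, p))
            return runner

        outcomes = [run_staircase(make_runner(), 42.0)[0] for _ in range(500)]
        freq41 = np.mean([o == 41.0 for o in outcomes])
        assert set(outcomes) == {41.0, 42.0}
        # 4 sigma of the exact binomial proportion at n = 500
        assert abs(freq41 - p_block_41) < 4 * np.sqrt(p_block_41 * (1 - p_block_41) / 500)
        assert sps.mode(outcomes).mode in (41.0, 42.0)

    def test_non_termination_raises(self):
        # always succeeding: the staircase descends to the 1 %MSO bound and
        # can never bracket a failing lower intensity
        with pytest.raises(StaircaseError):
            run_staircase(lambda x: 10, 40.0, max_blocks=30)

    def test_replay_rejects_protocol_violations(self):
        with pytest.raises(ValueError):
            determine_rmt([(45.0, 8), (50.0, 8)])  # should have stepped down


class TestFitIOCurve:
    TRUE = dict(floor=1.3, ceiling=3.4, mid=45.0, width=6.0)

    def _data(self, noise=0.0, rng=None):
        x = np.repeat(np.arange(30.0, 58.0, 3.0), 15)
        from scipy.special import ndtr

        y = self.TRUE["floor"] + (self.TRUE["ceiling"] - self.TRUE["floor"]) * ndtr(
            (x - self.TRUE["mid"]) / self.TRUE["width"]
        )
        if noise:
            y = y + rng.normal(0, noise, size=y.size)
        return x, y

    def test_zero_noise_recovery_to_four_significant_figures(self):
        x, y = self._data()
        fit = fit_io_curve(x, y)
        assert fit.converged
        assert fit.floor == pytest.approx(self.TRUE["floor"], rel=1e-4)
        assert fit.ceiling == pytest.approx(self.TRUE["ceiling"], rel=1e-4)
        assert fit.midpoint == pytest.approx(self.TRUE["mid"], rel=1e-4)
        assert fit.width == pytest.approx(self.TRUE["width"], rel=1e-4)

    def test_midpoint_slope_matches_numerical_derivative(self):
        x, y = self._data()
        fit = fit_io_curve(x, y)
        h = 1e-4
        num = (fit.predict(fit.midpoint + h) - fit.predict(fit.midpoint - h)) / (2 * h)
        assert abs(fit.midpoint_slope - num) < 1e-6

    def test_shift_equivariance(self):
        """Adding a constant to all log amplitudes shifts floor and ceiling,
        leaving midpoint, width and slope unchanged."""
        x, y = self._data(noise=0.05, rng=np.random.default_rng(8))
        f1 = fit_io_curve(x, y)
        f2 = fit_io_curve(x, y + 0.7)
        assert f2.floor - f1.floor == pytest.approx(0.7, abs=1e-3)
        assert f2.ceiling - f1.ceiling == pytest.approx(0.7, abs=1e-3)
        assert f2.midpoint == pytest.approx(f1.midpoint, abs=1e-2)
        assert f2.width == pytest.approx(f1.width, abs=1e-2)
        assert f2.midpoint_slope == pytest.approx(f1.midpoint_slope, rel=1e-3)

    def test_all_floored_data_not_converged(self):
        x = np.repeat(np.arange(30.0, 45.0, 3.0), 15)
        y = np.full(x.size, np.log10(20.0))
        fit = fit_io_curve(x, y)
        assert not fit.converged

    def test_too_few_intensities_rejected(self):
        with pytest.raises(ValueError):
            fit_io_curve([30.0, 33.0, 36.0], [1.0, 2.0, 3.0])


class TestRMAnova:
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-50, max_value=50),
                st.floats(min_value=-50, max_value=50),
            ),
            min_size=3,
            max_size=20,
        )
    )
    def test_f_equals_squared_paired_t(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if np.std(a - b, ddof=1) == 0:
            return
        res = rm_anova_two_level(a, b)
        t, p = sps.ttest_rel(a, b)
        assert res.f_statistic == pytest.approx(t * t, rel=1e-9, abs=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9, abs=1e-12)
        assert res.df == (1, len(pairs) - 1)

    def test_against_dedicated_rm_anova_implementation(self):
        """Cross-check F and p against pingouin's repeated-measures ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a = rng.normal(41.0, 6.0, 12)
        b = a - rng.normal(3.0, 1.5, 12)
        res = rm_anova_two_level(a, b)
        df = pd.DataFrame(
            {
                "y": np.r_[a, b],
                "cond": ["a"] * 12 + ["b"] * 12,
                "subj": list(range(12)) * 2,
            }
        )
        out = pingouin.rm_anova(data=df, dv="y", within="cond", subject="subj")
        assert res.f_statistic == pytest.approx(float(out["F"].iloc[0]), rel=1e-6)
        assert res.p_value == pytest.approx(float(out["p_unc"].iloc[0]), rel=1e-6)

    def test_identical_conditions(self):
        a = np.arange(5.0)
        res = rm_anova_two_level(a, a.copy())
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_nonzero_difference_capped(self):
        a = np.arange(5.0)
        res = rm_anova_two_level(a + 2.0, a)
        assert res.capped and np.isinf(res.f_statistic)


class TestCohensD:
    def test_equal_means_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a[::-1]) == pytest.approx(0.0)

    def test_pooled_variant_from_summary_statistics(self):
        """Condition means 41.34/38.00 with SDs 6.07/5.91 give a pooled-SD
        effect size of 3.34 / 5.9905 = 0.5575."""
        a = np.array([41.34 - 6.07 / np.sqrt(2), 41.34 + 6.07 / np.sqrt(2)])
        b = np.array([38.00 - 5.91 / np.sqrt(2), 38.00 + 5.91 / np.sqrt(2)])
        d = cohens_d(a, b, variant="pooled")
        assert d == pytest.approx(3.34 / np.sqrt((6.07**2 + 5.91**2) / 2), rel=1e-9)
        assert d == pytest.approx(0.5575, abs=5e-4)

    def test_difference_sd_variant(self):
        """A paired difference of mean 3.34 and SD 6.30 gives d = 0.53."""
        base = np.array([10.0, 20.0])
        diff = np.array([3.34 - 6.30 / np.sqrt(2), 3.34 + 6.30 / np.sqrt(2)])
        d = cohens_d(base + diff, base, variant="difference")
        assert d == pytest.approx(3.34 / 6.30, rel=1e-9)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestLatencyByAmplitude:
    def test_single_populated_bin(self):
        res = latency_by_amplitude([500.0] * 5, [22.0] * 5)
        assert set(res) == {500.0}
        assert res[500.0] == 22.0

    def test_band_edges_multiplicative(self):
        res = latency_by_amplitude([50 / 1.5, 50 * 1.5, 76.0], [20.0, 21.0, 22.0])
        assert res[50.0] == pytest.approx(20.5)

    def test_undetected_trials_ignored(self):
        res = latency_by_amplitude([500.0, 500.0], [None, 23.0])
        assert res[500.0] == 23.0


class TestBlocksFromTrials:
    def test_session_grouping_and_replay(self, rng):
        cfg = CohortConfig(seed=4)
        p = generate_cohort(cfg)[0]
        from pwmtms.study import generate_rmt_session

        trials = generate_rmt_session(p, "magstim", rng)
        blocks = blocks_from_trials(trials)
        assert all(0 <= s <= 10 for _, s in blocks)
        est = determine_rmt(blocks, participant=p.participant_id, device="magstim")
        assert est.rmt in [b[0] for b in blocks]
        # the estimate's defining property: >= 5/10 at rmt, < 5/10 one below
        last = {i: s for i, s in blocks}
        assert last[est.rmt] >= 5
        if est.rmt - 1.0 in last:
            assert last[est.rmt - 1.0] < 5
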