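import numpy as np
import pytest

from miirkit.core import BeatAnnotation
from miirkit.synthetic import SyntheticConfig, make_stimulus_track, simulate_trial
from miirkit.tempo import (
    TempoMatrix,
    aggregate_tempo,
    autocorr_tempo_curve,
    bar_epochs,
    default_tempo_grid,
    erp,
    fourier_tempogram,
    sliding_tempo_matrix,
    tempo_error,
    tempo_histogram,
)

RATE = 64.0


def downbeat_annotation(times):
    times = np.asarray(times, dtype=float)
    return BeatAnnotation(times, times)


class TestBarEpochs:
    def test_slow_bars_every_second_epoch_rejected(self):
        # bar length 2.308 s < 2.5 s window -> alternating rejection
        times = np.arange(0.2, 20.0, 4 * 60.0 / 104.0)
        ep = bar_epochs(np.zeros(int(25 * RATE)), downbeat_annotation(times), RATE)
        assert len(ep) == (len(times) + 1) // 2
        assert np.allclose(ep.anchors, times[::2])

    def test_long_bars_no_rejection(self):
        times = np.arange(0.5, 18.0, 3.0)
        ep = bar_epochs(np.zeros(int(21 * RATE)), downbeat_annotation(times), RATE)
        assert len(ep) == len(times)

    def test_epoch_length_160_samples(self):
        ep = bar_epochs(np.zeros(1000), downbeat_annotation([5.0]), RATE)
        assert ep.epochs.shape == (1, 160)

    def test_no_downbeats_empty(self):
        ep = bar_epochs(np.zeros(100), BeatAnnotation(np.array([]), np.array([])), RATE)
        assert len(ep) == 0

    def test_accepted_intervals_never_overlap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = np.sort(rng.uniform(0.5, 28.0, 12))
            times = times[np.concatenate([[True], np.diff(times) > 0.05])]
            ep = bar_epochs(np.zeros(int(30 * RATE)), downbeat_annotation(times), RATE)
            for (s1, e1), (s2, e2) in zip(ep.intervals[:-1], ep.intervals[1:]):
                assert e1 <= s2  # half-open, disjoint


class TestErp:
    def test_identical_epochs(self):
        ep = bar_epochs(np.tile(np.arange(160.0), 4), downbeat_annotation([0.2, 2.7]), RATE)
        assert np.allclose(erp(ep), ep.epochs[0])

    def test_opposite_epochs_cancel(self):
        from miirkit.tempo import EpochSet

        v = np.random.default_rng(0).standard_normal(50)
        ep = EpochSet(np.stack([v, -v]), (0.1, 2.4), np.zeros(2), np.zeros((2, 2), int))
        assert np.allclose(erp(ep), 0.0)

    def test_matches_loop_oracle(self):
        from miirkit.tempo import EpochSet

        e = np.random.default_rng(1).standard_normal((5, 30))
        ep = EpochSet(e, (0.1, 2.4), np.zeros(5), np.zeros((5, 2), int))
        assert np.allclose(erp(ep), sum(e[i] for i in range(5)) / 5)


class TestAutocorrCurve:
    def test_one_second_period_peaks_at_60_bpm_or_subharmonic(self):
        # a pure sinusoid scores maximally at every multiple of its period,
        # so the argmax lands on 60 BPM or an exact subharmonic of it
        t = np.arange(0, 10, 1 / RATE)
        x = np.sin(2 * np.pi * t)
        grid, scores = autocorr_tempo_curve(x, RATE)
        peak = grid[np.argmax(scores)]
        assert peak in (30.0, 60.0, 120.0)
        assert scores[np.argmin(np.abs(grid - 60.0))] == pytest.approx(scores.max(), abs=0.02)

    def test_white_noise_scores_small(self):
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(512)
            _, scores = autocorr_tempo_curve(x, RATE)
            assert np.abs(scores).max() < 0.2

    def test_matches_brute_force_at_integer_lags(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        lags = np.arange(13, 150, 7)
        grid = 60.0 * RATE / lags  # tempi with exactly integer lags
        order = np.argsort(grid)
        tempi, scores = autocorr_tempo_curve(x, RATE, grid[order])
        xc = x - x.mean()
        var = np.mean(xc**2)
        for tempo, score in zip(tempi, scores):
            lag = int(round(60.0 * RATE / tempo))
            expected = sum(xc[t] * xc[t + lag] for t in range(x.size - lag)) / (
                (x.size - lag) * var
            )
            assert score == pytest.approx(expected, abs=1e-10)


class TestSlidingMatrix:
    def test_row_count_formula(self):
        x = np.random.default_rng(0).standard_normal(640)
        m = sliding_tempo_matrix(x, RATE)
        assert m.scores.shape[0] == (640 - 160) // 5 + 1 == 97

    def test_stationary_sinusoid_rows_equal(self):
        # 4 Hz -> 10 full periods per window, so every window position sees
        # the same statistics
        t = np.arange(0, 10, 1 / RATE)
        grid = default_tempo_grid(30, 300, 0.5)  # lags with >= 0.5 s overlap
        m = sliding_tempo_matrix(np.sin(2 * np.pi * 4 * t), RATE, tempo_grid=grid)
        assert np.allclose(m.scores, m.scores[0], atol=0.15)

    def test_rows_match_slice_curves(self):
        x = np.random.default_rng(1).standard_normal(400)
        m = sliding_tempo_matrix(x, RATE)
        for k in (0, 10, len(m.offsets) - 1):
            off = m.offsets[k]
            _, expected = autocorr_tempo_curve(x[off : off + 160], RATE, m.tempo_grid)
            assert np.allclose(m.scores[k], expected)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sliding_tempo_matrix(np.zeros(100), RATE)


class TestAggregateTempo:
    def constructed_matrix(self, peak=70.0, harmonic_gain=0.6):
        grid = default_tempo_grid(24, 300, 0.5)
        scores = np.full((10, grid.size), 0.01)
        scores[:, np.argmin(np.abs(grid - peak))] = 1.0
        scores[:, np.argmin(np.abs(grid - 2 * peak))] = harmonic_gain
        return TempoMatrix(np.arange(10), grid, scores)

    def test_dominant_pair_returns_stronger_member(self):
        m = self.constructed_matrix(70.0, harmonic_gain=0.6)
        assert aggregate_tempo(m) == 70.0
        m2 = self.constructed_matrix(70.0, harmonic_gain=1.5)
        assert aggregate_tempo(m2) == 140.0

    def test_all_equal_scores_lowest_pair(self):
        grid = default_tempo_grid(24, 300, 0.5)
        m = TempoMatrix(np.arange(3), grid, np.ones((3, grid.size)))
        assert aggregate_tempo(m) == 24.0  # lowest harmonic pair, lower member ties

    def test_synthetic_bar_locked_trial_recovered(self):
        from miirkit.core import default_stimuli

        meta = next(s for s in default_stimuli() if s.id == 4)  # bar tempo 40
        cfg = SyntheticConfig(snr=20.0)
        rng = np.random.default_rng(0)
        mixing = (np.abs(rng.standard_normal((64, 3))) + 0.3)
        mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
        trial, _ = simulate_trial(meta, mixing, 20.0, 11, cfg)
        est = aggregate_tempo(sliding_tempo_matrix(trial.data.mean(axis=0), RATE))
        assert tempo_error(est, meta.bar_tempo_bpm) <= 0.5


class TestTempoError:
    @pytest.mark.parametrize(
        "est,true,expected", [(100, 100, 0.0), (106, 212, 0.0), (90, 100, 10.0), (80, 40, 0.0)]
    )
    def test_harmonic_tolerance(self, est, true, expected):
        assert tempo_error(est, true) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            tempo_error(0.0, 100.0)


class TestFourierTempogram:
    def click_train(self, bpm, seconds=10.0):
        # smoothed clicks: pure impulses carry equally strong harmonics,
        # which would make the fundamental/harmonic argmax a coin flip
        n = int(seconds * RATE)
        x = np.zeros(n)
        period = 60.0 / bpm * RATE
        idx = np.round(np.arange(0, n - 1, period)).astype(int)
        x[idx] = 1.0
        return np.convolve(x, np.hanning(9), mode="same")

    def test_click_train_peaks_at_its_tempo(self):
        m = fourier_tempogram(self.click_train(120.0), RATE)
        _, peak = tempo_histogram(m)
        assert peak == pytest.approx(120.0, abs=0.5)

    def test_dc_input_near_zero(self):
        m = fourier_tempogram(np.full(640, 3.0), RATE)
        assert np.abs(m.scores).max() < 1e-9

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(320)
        grid = np.array([50.0, 100.0, 200.0])
        m = fourier_tempogram(x, RATE, tempo_grid=grid)
        win = 160
        hann = np.hanning(win)
        for r, off in enumerate(m.offsets):
            seg = x[off : off + win] - x[off : off + win].mean()
            for j, tempo in enumerate(grid):
                f = tempo / 60.0
                z = sum(
                    seg[t] * hann[t] * np.exp(-2j * np.pi * f * t / RATE) for t in range(win)
                )
                assert m.scores[r, j] == pytest.approx(abs(z) / win, abs=1e-10)

    def test_agrees_with_autocorrelation_on_clean_periodic_input(self):
        x = self.click_train(100.0, seconds=12.0)
        grid = default_tempo_grid(40, 240, 1.0)
        peak_ac = aggregate_tempo(sliding_tempo_matrix(x, RATE, tempo_grid=grid))
        _, peak_ft = tempo_histogram(fourier_tempogram(x, RATE, tempo_grid=grid))
        assert tempo_error(peak_ac, peak_ft) <= 1.0


class TestHistogram:
    def test_single_row_matrix(self):
        grid = default_tempo_grid(24, 60, 1.0)
        row = np.random.default_rng(0).uniform(size=grid.size)
        m = TempoMatrix(np.zeros(1), grid, row[None, :])
        hist, peak = tempo_histogram(m)
        assert np.allclose(hist, row)
        assert peak == grid[np.argmax(row)]

    def test_histogram_averaging_is_elementwise_mean(self):
        grid = default_tempo_grid(24, 60, 1.0)
        rng = np.random.default_rng(1)
        m1 = TempoMatrix(np.zeros(2), grid, rng.uniform(size=(2, grid.size)))
        m2 = TempoMatrix(np.zeros(2), grid, rng.uniform(size=(2, grid.size)))
        h1, _ = tempo_histogram(m1)
        h2, _ = tempo_histogram(m2)
        assert np.allclose((h1 + h2) / 2, np.mean([h1, h2], axis=0))


class TestJitterDegradesErp:
    def test_jittered_anchors_reduce_autocorrelation_peak(self):
        # bar-locked signal; jittering the epoch anchors must lower the
        # ERP's autocorrelation score at the bar tempo on average
        from miirkit.core import StimulusMeta

        meta = StimulusMeta(21, "test", 3, 30.0, 120.0)  # bar tempo 40 -> 1.5 s bars
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            env, ann = make_stimulus_track(meta, RATE)
            t = np.arange(env.size) / RATE
            signal = np.zeros_like(t)
            for d in ann.downbeat_times_s:
                signal += np.exp(-((t - d) ** 2) / (2 * 0.05**2))
            signal += 0.3 * rng.standard_normal(signal.size)
            clean = bar_epochs(signal, ann, RATE)
            jit_times = ann.downbeat_times_s + rng.uniform(-0.2, 0.2, ann.downbeat_times_s.size)
            jit_times = np.sort(np.clip(jit_times, 0.11, None))
            jit = bar_epochs(signal, BeatAnnotation(jit_times, jit_times), RATE)
            grid = np.array([40.0])
            _, s_clean = autocorr_tempo_curve(erp(clean), RATE, grid)
            _, s_jit = autocorr_tempo_curve(erp(jit), RATE, grid)
            deltas.append(s_clean[0] - s_jit[0])
        assert np.mean(deltas) > 0
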