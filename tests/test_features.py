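import numpy as np
import pytest

from somnoscore.core import EpochGrid, SignalRecord, make_epoch_grid
from somnoscore.features import (OrpLikeliness, Segment, band_powers,
                                 compute_densities, count_snores,
                                 detect_eye_movements, detect_spindles,
                                 emg_background, heart_rate_features,
                                 position_change_flags, sao2_stats,
                                 spindle_amplitude_score, spindle_factor,
                                 spindle_frequency_score,
                                 zero_crossing_segments)

FS = 100.0


def _sine(freq, duration=30.0, fs=FS, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestBandPowers:
    def test_zero_signal_has_zero_power(self):
        assert np.allclose(band_powers(np.zeros(3000), FS), 0.0)

    @pytest.mark.parametrize("freq,band_idx", [(1.0, 0), (4.0, 1),
                                               (10.0, 2), (20.0, 3)])
    def test_pure_tone_concentrates_in_its_band(self, freq, band_idx):
        p = band_powers(_sine(freq), FS)
        assert p[band_idx] / p.sum() >= 0.95

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_powers(np.ones(100), 50.0)


class TestZeroCrossingSegments:
    def test_pure_sine_recovers_frequency(self):
        segs = zero_crossing_segments(_sine(13.0, fs=200.0), 200.0)
        freqs = [s.frequency for s in segs[1:-1]]  # interior half-waves
        assert abs(np.median(freqs) - 13.0) < 0.2

    def test_constant_sign_yields_single_segment(self):
        segs = zero_crossing_segments(np.ones(500), FS)
        assert len(segs) == 1 and segs[0].duration == pytest.approx(5.0)

    def test_alternating_signal_gives_nyquist_frequency(self):
        x = np.tile([1.0, -1.0], 50)
        segs = zero_crossing_segments(x, FS)
        interior = [s for s in segs[1:-1]]
        assert np.allclose([s.frequency for s in interior], 50.0, rtol=1e-6)


class TestSpindleScores:
    @pytest.mark.parametrize("f,score", [
        (13.0, 1.0), (12.0, 1.0), (11.25, 0.5), (10.5, 0.0), (16.0, 0.0),
        (15.0, 0.5), (9.0, 0.0), (20.0, 0.0)])
    def test_frequency_score_piecewise_values(self, f, score):
        assert spindle_frequency_score(f) == pytest.approx(score)

    @pytest.mark.parametrize("a,score", [
        (4.0, 1.0), (8.0, 0.5), (0.0, 0.0), (12.0, 0.0), (2.0, 0.5),
        (20.0, 0.0)])
    def test_amplitude_score_piecewise_values(self, a, score):
        assert spindle_amplitude_score(a) == pytest.approx(score)

    def test_scores_bounded_and_zero_outside_support(self):
        f = np.linspace(0, 40, 4001)
        sf = spindle_frequency_score(f)
        assert np.all((sf >= 0) & (sf <= 1))
        assert np.all(sf[(f < 10.5) | (f >= 16)] == 0)
        a = np.linspace(0, 30, 3001)
        sa = spindle_amplitude_score(a)
        assert np.all((sa >= 0) & (sa <= 1))
        assert np.all(sa[a >= 12] == 0)

    def test_scores_are_continuous(self):
        grid = np.linspace(0, 40, 40001)
        assert np.max(np.abs(np.diff(spindle_frequency_score(grid)))) < 1e-2
        assert np.max(np.abs(np.diff(spindle_amplitude_score(grid)))) < 1e-2


def _segment(f, a):
    return Segment(duration=1.0 / (2.0 * f), amplitude=a, start_index=0)


class TestSpindleFactor:
    def test_constant_spindle_band_run_scores_zero(self):
        segs = [_segment(13.0, 4.0)] * 11
        assert spindle_factor(segs, 5) == 0.0

    def test_zero_score_denominator_maps_to_inf(self):
        segs = [_segment(9.0, 4.0)] * 11
        assert spindle_factor(segs, 5) == np.inf

    def test_unit_scores_expose_frequency_variance(self):
        segs = [_segment(f, 4.0) for f in (12.5, 13.0, 13.5)]
        # hand-computed population variance of {12.5, 13, 13.5}
        expected = ((0.5) ** 2 + 0.0 + (0.5) ** 2) / 3.0
        assert spindle_factor(segs, 1) == pytest.approx(expected)


class TestDetectSpindles:
    background = 80.0 * _sine(2.0)

    @staticmethod
    def _with_bursts(background, starts_s, fs=FS):
        x = background.copy()
        tt = np.arange(int(fs)) / fs
        burst = 4.0 * np.sin(2 * np.pi * 13.0 * tt)
        for s in starts_s:
            i = int(s * fs)
            x[i:i + int(fs)] += burst
        return x

    def test_single_injected_burst_found(self):
        x = self._with_bursts(self.background, [10.0])
        assert detect_spindles(x, FS) == 1

    def test_pure_slow_background_yields_none(self):
        assert detect_spindles(self.background, FS) == 0

    def test_two_separated_bursts_found(self):
        x = self._with_bursts(self.background, [5.0, 11.0])
        assert detect_spindles(x, FS) == 2

    @pytest.mark.parametrize("scale", [0.5, 2.0, 5.0])
    def test_invariant_to_background_rescaling(self, scale):
        x = self._with_bursts(scale * self.background, [10.0, 20.0])
        assert detect_spindles(x, FS) == 2


class TestEyeMovements:
    @staticmethod
    def _channels(shape, start_s=10.0, mirrored=True, fs=FS):
        n = int(30 * fs)
        left, right = np.zeros(n), np.zeros(n)
        i = int(start_s * fs)
        left[i:i + shape.size] += shape
        right[i:i + shape.size] += (-shape if mirrored else shape)
        grid = make_epoch_grid(30.0)
        return (SignalRecord("L", fs, left), SignalRecord("R", fs, right),
                grid)

    @staticmethod
    def _sawtooth(duration=0.2, amplitude=60.0, fs=FS):
        rise = max(2, int(0.02 * fs))
        total = int(duration * fs)
        return np.concatenate([np.linspace(0, amplitude, rise),
                               np.linspace(amplitude, 0, total - rise)])

    @staticmethod
    def _slow_halfwave(duration=1.2, amplitude=60.0, fs=FS):
        n = int(duration * fs)
        return amplitude * np.sin(np.pi * np.arange(n) / n)

    def test_sharp_mirrored_deflection_is_rem(self):
        rems, sems = detect_eye_movements(*self._channels(self._sawtooth()))
        assert (rems.sum(), sems.sum()) == (1, 0)

    def test_slow_mirrored_halfwave_is_sem(self):
        rems, sems = detect_eye_movements(
            *self._channels(self._slow_halfwave()))
        assert (rems.sum(), sems.sum()) == (0, 1)

    def test_same_signed_deflections_are_not_conjugate(self):
        rems, sems = detect_eye_movements(
            *self._channels(self._sawtooth(), mirrored=False))
        assert (rems.sum(), sems.sum()) == (0, 0)

    def test_channel_mismatch_rejected(self):
        left, right, grid = self._channels(self._sawtooth())
        right = SignalRecord("R", 200.0, right.samples)
        with pytest.raises(ValueError, match="sampling rate"):
            detect_eye_movements(left, right, grid)


class TestEmgBackground:
    def test_stationary_noise_centres_at_one(self, rng):
        sig = SignalRecord("EMG", 200.0, rng.standard_normal(200 * 300) * 5)
        out = emg_background([sig], make_epoch_grid(300))
        assert np.all(np.abs(out - 1.0) < 0.1)

    def test_elevated_epoch_scales_linearly(self, rng):
        x = rng.standard_normal(200 * 30 * 100) * 5
        x[200 * 30 * 50:200 * 30 * 51] *= 3.0
        out = emg_background([SignalRecord("EMG", 200.0, x)],
                             make_epoch_grid(3000))
        assert out[50] == pytest.approx(3.0, rel=0.15)
        assert np.median(out) == pytest.approx(1.0, abs=1e-9)

    def test_single_epoch_is_its_own_median(self, rng):
        sig = SignalRecord("EMG", 200.0, rng.standard_normal(200 * 30) * 5)
        out = emg_background([sig], make_epoch_grid(30))
        assert out[0] == pytest.approx(1.0)

    def test_empty_channel_list_rejected(self):
        with pytest.raises(ValueError, match="no EMG"):
            emg_background([], make_epoch_grid(30))


class TestHeartRate:
    def test_constant_rate_sits_at_midrank(self):
        q, c = heart_rate_features([60.0] * 5)
        assert np.allclose(q, 0.5) and np.allclose(c, 0.0)

    def test_midrank_quantiles(self):
        q, _ = heart_rate_features([50.0, 60.0, 70.0])
        np.testing.assert_allclose(q, [1 / 6, 1 / 2, 5 / 6])

    def test_change_is_first_difference(self):
        _, c = heart_rate_features([60.0, 65.0])
        np.testing.assert_allclose(c, [0.0, 5.0])

    def test_quantile_monotone_in_rate(self, rng):
        hr = rng.uniform(40, 100, 200)
        q, _ = heart_rate_features(hr)
        order = np.argsort(hr)
        assert np.all(np.diff(q[order]) >= 0)


class TestSimpleFeatures:
    def test_position_change_flags(self):
        np.testing.assert_array_equal(
            position_change_flags(["back", "back", "left", "left"]),
            [0, 0, 1, 0])
        assert np.all(position_change_flags(["back"] * 5) == 0)
        np.testing.assert_array_equal(position_change_flags(["belly"]), [0])

    def test_unknown_position_label_rejected(self):
        with pytest.raises(ValueError, match="sitting"):
            position_change_flags(["back", "sitting"])

    @pytest.mark.parametrize("samples,expected", [
        ([97.0] * 10, (97.0, 0.0)),
        ([94.0, 98.0], (96.0, 4.0)),
        ([97.0, 97.0, 10.0], (97.0, 0.0))])
    def test_sao2_stats(self, samples, expected):
        assert sao2_stats(samples) == pytest.approx(expected)

    def test_sao2_all_dropout_flagged_missing(self):
        m, v = sao2_stats([10.0, 20.0])
        assert np.isnan(m) and np.isnan(v)

    def test_densities_are_track_means(self):
        d = compute_densities([0, 2, 4], [0, 0, 0], [1, 1, 1])
        assert (d.spindle_density, d.rem_density, d.sem_density) == (2.0, 0.0, 1.0)

    def test_snore_events_binned_per_epoch(self):
        counts = count_snores(EpochGrid(n_epochs=2), snore_events=[5, 12, 45])
        np.testing.assert_array_equal(counts, [2, 1])

    def test_silent_microphone_counts_nothing(self):
        mic = SignalRecord("MIC", 100.0, np.zeros(100 * 60))
        assert np.all(count_snores(EpochGrid(n_epochs=2), microphone=mic) == 0)

    def test_empty_event_list(self):
        assert np.all(count_snores(EpochGrid(n_epochs=3), snore_events=[]) == 0)

    def test_no_snore_input_rejected(self):
        with pytest.raises(ValueError):
            count_snores(EpochGrid(n_epochs=2))


class TestOrpLikeliness:
    @staticmethod
    def _clustered_powers(rng, n_per_cluster, centres):
        powers, labels = [], []
        for c, (centre, stage) in enumerate(centres):
            powers.append(rng.normal(centre, 0.01, size=(n_per_cluster, 4)))
            labels += [stage] * n_per_cluster
        return np.vstack(powers), labels

    def test_degenerate_lookup_gives_certain_score(self, rng):
        # ranks are within-recording, so score a recording with the training
        # power distribution: its low cluster carries a W-only signature
        powers, labels = self._clustered_powers(
            rng, 40, [((1, 1, 1, 1), "W"), ((10, 10, 10, 10), "N2")])
        model = OrpLikeliness().fit(powers, labels)
        scores = model.score_windows(powers)
        np.testing.assert_allclose(scores[:40, 0], 1.0)
        np.testing.assert_allclose(scores[:40, 1:], 0.0)

    def test_unseen_signature_backs_off_to_priors(self, rng):
        powers, labels = self._clustered_powers(
            rng, 30, [((1, 1, 1, 1), "W"), ((10, 10, 10, 10), "N2"),
                      ((10, 10, 10, 10), "N2")])
        model = OrpLikeliness().fit(powers, labels)
        # a signature never seen in training: mid-way cluster
        scores = model.score_windows(np.full((5, 4), 5.0))
        np.testing.assert_allclose(scores, np.tile(model.priors_, (5, 1)))
        np.testing.assert_allclose(model.priors_, [1 / 3, 0, 2 / 3, 0, 0])

    def test_uniform_training_labels_score_point_two(self):
        powers = np.ones((25, 4))
        labels = ["W", "N1", "N2", "N3", "R"] * 5
        model = OrpLikeliness().fit(powers, labels)
        np.testing.assert_allclose(model.score_windows(np.ones((3, 4))), 0.2)

    def test_untrained_lookup_rejected(self):
        with pytest.raises(ValueError, match="untrained"):
            OrpLikeliness().score_windows(np.ones((3, 4)))
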