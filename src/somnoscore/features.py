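"""Per-epoch feature extraction from raw PSG signals.

One row of the feature record per 30-s epoch:

* five ORP-style stage-likeliness scores from ranked EEG band powers
  (delta 0-2.5, theta 2.5-6.8, alpha 6.8-14, beta 14-35 Hz),
* sleep-spindle count from a zero-crossing segment detector with
  piecewise-linear frequency/amplitude scoring,
* rapid (REM) and slow (SEM) conjugate eye-movement counts from the two EOG
  channels,
* background EMG (filtered, morphologically opened, median-centred),
* heart-rate quantile and epoch-to-epoch change,
* SaO2 mean and variance, body-position change flag, snore count,

plus per-recording densities (mean events/epoch) for spindles, REMs and SEMs,
which contextualise the counts for patient-dependent emission modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .core import (EpochGrid, N_STAGES, STAGES, SignalRecord, partition_epochs,
                   stage_codes)

# EEG frequency bands (Hz).  These deliberately differ slightly from the AASM
# textbook band edges; they are the edges the staging features are defined on.
EEG_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 2.5), (2.5, 6.8), (6.8, 14.0), (14.0, 35.0))
BAND_NAMES = ("delta", "theta", "alpha", "beta")

POSITION_LABELS = ("standing", "belly", "back", "left", "right")

#: Columns of the per-epoch feature table, in declared order.
FEATURE_COLUMNS = (
    "orp_W", "orp_N1", "orp_N2", "orp_N3", "orp_R",
    "n_spindles", "n_rems", "n_sems",
    "emg_background", "hr_quantile", "hr_change",
    "sao2_mean", "sao2_var", "position_change", "n_snores",
)

#: Per-recording density columns carried on every row of the feature table.
DENSITY_COLUMNS = ("spindle_density", "rem_density", "sem_density")


# ---------------------------------------------------------------------------
# EEG band powers
# ---------------------------------------------------------------------------

def band_powers(eeg_epoch, fs: float) -> np.ndarray:
    """Power of an EEG window in the four staging bands.

    Integrates the periodogram PSD over each band.  Requires ``fs >= 70`` so
    the beta band (up to 35 Hz) is below Nyquist.
    """
    x = np.asarray(eeg_epoch, dtype=float)
    if x.size == 0:
        raise ValueError("empty EEG epoch")
    if fs < 70.0:
        raise ValueError("beta band exceeds Nyquist: need fs >= 70 Hz")
    freqs, psd = signal.periodogram(x, fs=fs, detrend=False)
    out = np.empty(len(EEG_BANDS))
    for i, (lo, hi) in enumerate(EEG_BANDS):
        sel = (freqs >= lo) & (freqs < hi)
        out[i] = np.trapezoid(psd[sel], freqs[sel]) if sel.sum() > 1 else psd[sel].sum()
    return out


def windowed_band_powers(eeg: np.ndarray, fs: float, window_s: float = 3.0) -> np.ndarray:
    """Band powers for consecutive ``window_s`` windows of a whole recording."""
    spw = int(round(window_s * fs))
    n = eeg.size // spw
    if n == 0:
        raise ValueError("recording shorter than one analysis window")
    wins = np.asarray(eeg[: n * spw], dtype=float).reshape(n, spw)
    return np.vstack([band_powers(w, fs) for w in wins])


# ---------------------------------------------------------------------------
# ORP-style stage likeliness
# ---------------------------------------------------------------------------

class OrpLikeliness(BaseEstimator):
    """Stage-likeliness scores from ranked EEG band powers.

    Approximates an odds-ratio-product style score: each 3-s window's four
    band powers are converted to within-recording decile ranks, concatenated
    into a 4-digit signature, and a lookup table maps each signature to the
    relative frequency of the five stages among training windows carrying it.
    An epoch's score is the mean over its ten windows; signatures never seen
    in training back off to the training stage priors.

    The five per-epoch scores each live in [0, 1] but are independent
    likelinesses — they need not sum to 1.
    """

    def __init__(self, n_bins: int = 10, window_s: float = 3.0):
        self.n_bins = n_bins
        self.window_s = window_s

    # -- rank signatures ----------------------------------------------------
    def _signatures(self, powers: np.ndarray, groups: np.ndarray) -> np.ndarray:
        powers = np.asarray(powers, dtype=float)
        sig = np.zeros(len(powers), dtype=np.int64)
        for g in np.unique(groups):
            sel = groups == g
            for b in range(powers.shape[1]):
                col = powers[sel, b]
                edges = np.quantile(col, np.linspace(0, 1, self.n_bins + 1)[1:-1])
                ranks = np.searchsorted(edges, col, side="right")
                sig[sel] = sig[sel] * self.n_bins + ranks
        return sig

    def fit(self, powers, stages, groups=None):
        """Learn the signature -> stage-frequency table.

        Parameters
        ----------
        powers : (n_windows, 4) band powers of labelled 3-s training windows.
        stages : stage label (or code) per window.
        groups : recording id per window; ranks are taken within recordings.
        """
        powers = np.asarray(powers, dtype=float)
        y = stage_codes(stages) if not np.issubdtype(
            np.asarray(stages).dtype, np.integer) else np.asarray(stages)
        groups = np.zeros(len(powers), dtype=np.intp) if groups is None \
            else np.asarray(groups)
        sig = self._signatures(powers, groups)
        table: dict[int, np.ndarray] = {}
        for s, c in zip(sig, y):
            table.setdefault(int(s), np.zeros(N_STAGES))[c] += 1.0
        self.table_ = {k: v / v.sum() for k, v in table.items()}
        prior = np.bincount(y, minlength=N_STAGES).astype(float)
        self.priors_ = prior / prior.sum()
        return self

    def score_windows(self, powers, groups=None) -> np.ndarray:
        """Per-window 5-vector of stage likelinesses (n_windows x 5)."""
        if not hasattr(self, "table_"):
            raise ValueError("OrpLikeliness is untrained; call fit first")
        powers = np.asarray(powers, dtype=float)
        groups = np.zeros(len(powers), dtype=np.intp) if groups is None \
            else np.asarray(groups)
        sig = self._signatures(powers, groups)
        return np.vstack([self.table_.get(int(s), self.priors_) for s in sig])

    def epoch_scores(self, powers, groups=None,
                     epoch_length: float = 30.0) -> np.ndarray:
        """Mean window score per epoch (n_epochs x 5)."""
        scores = self.score_windows(powers, groups)
        per_epoch = int(round(epoch_length / self.window_s))
        n = scores.shape[0] // per_epoch
        return scores[: n * per_epoch].reshape(n, per_epoch, N_STAGES).mean(axis=1)


# ---------------------------------------------------------------------------
# Sleep spindles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A between-zero-crossings signal segment.

    The half-wave duration ``d`` maps to an equivalent oscillation frequency
    ``f = 1 / (2 d)``; ``a`` is the maximum absolute amplitude inside the
    segment.
    """

    duration: float
    amplitude: float
    start_index: int

    @property
    def frequency(self) -> float:
        return 1.0 / (2.0 * self.duration)


def zero_crossing_segments(x, fs: float) -> list[Segment]:
    """Partition a signal into segments between successive zero-crossings.

    Crossing positions are linearly interpolated between samples, so segment
    durations (hence the equivalent frequencies ``1/(2d)``) have sub-sample
    precision — at sleep-lab sampling rates the quantisation of whole-sample
    crossings would smear a 13 Hz oscillation across 12.5 and 16.7 Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    sgn = np.sign(x)
    # carry previous sign through exact zeros so they don't split segments
    for i in range(1, sgn.size):
        if sgn[i] == 0:
            sgn[i] = sgn[i - 1]
    change = np.flatnonzero(np.diff(sgn) != 0) + 1
    crossings = [(i - 1) + x[i - 1] / (x[i - 1] - x[i]) for i in change]
    bounds = np.concatenate(([0.0], crossings, [float(x.size)]))
    out = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 <= t0:
            continue
        i0, i1 = int(np.ceil(t0)), int(np.ceil(t1))
        chunk = x[i0:i1] if i1 > i0 else x[min(i0, x.size - 1):min(i0, x.size - 1) + 1]
        out.append(Segment(duration=(t1 - t0) / fs,
                           amplitude=float(np.max(np.abs(chunk))),
                           start_index=int(np.floor(t0))))
    return out


def spindle_frequency_score(f) -> np.ndarray | float:
    """Piecewise-linear spindle frequency score.

    1 on the 12-14 Hz plateau, falling linearly to 0 at 10.5 and 16 Hz,
    0 outside.
    """
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    out = np.where((f >= 10.5) & (f < 12.0), (2.0 / 3.0) * (f - 10.5), out)
    out = np.where((f >= 12.0) & (f < 14.0), 1.0, out)
    out = np.where((f >= 14.0) & (f < 16.0), 1.0 - 0.5 * (f - 14.0), out)
    return out if out.ndim else float(out)


def spindle_amplitude_score(a) -> np.ndarray | float:
    """Piecewise-linear spindle amplitude score, peaking at 4 uV, 0 beyond 12 uV."""
    a = np.asarray(a, dtype=float)
    out = np.zeros_like(a)
    out = np.where((a >= 0.0) & (a < 4.0), a / 4.0, out)
    out = np.where((a >= 4.0) & (a < 12.0), 1.0 - (a - 4.0) / 8.0, out)
    return out if out.ndim else float(out)


def spindle_factor(segments: list[Segment], j: int, half_window: int = 5) -> float:
    """Spindle factor of segment ``j``: local frequency variance over the
    combined frequency/amplitude score.

    Low values mean the segment sits in a run of near-constant spindle-band
    frequency at spindle-like amplitude.  A zero frequency or amplitude score
    maps to ``+inf`` (certainly not a spindle).  The +-5-segment window is
    truncated at the epoch boundaries.
    """
    if not segments:
        raise ValueError("no segments")
    lo, hi = max(0, j - half_window), min(len(segments), j + half_window + 1)
    freqs = np.array([s.frequency for s in segments[lo:hi]])
    denom = (spindle_frequency_score(segments[j].frequency)
             * spindle_amplitude_score(segments[j].amplitude))
    if denom <= 0.0:
        return np.inf
    return float(np.var(freqs) / denom)


def detect_spindles(eeg_epoch, fs: float, factor_threshold: float = 1.0,
                    min_duration: float = 0.5,
                    band: tuple[float, float] = (9.0, 17.0)) -> int:
    """Count sleep spindles in one EEG epoch.

    The epoch is band-passed around the spindle band (so a low-amplitude
    burst is visible under a large slow background), segmented at
    zero-crossings, and each segment scored by :func:`spindle_factor`.
    Maximal runs of segments below ``factor_threshold`` lasting at least
    ``min_duration`` seconds count as one spindle each.
    """
    x = np.asarray(eeg_epoch, dtype=float)
    if fs < 70.0:
        raise ValueError("beta band exceeds Nyquist: need fs >= 70 Hz")
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x)
    segments = zero_crossing_segments(xf, fs)
    factors = np.array([spindle_factor(segments, j) for j in range(len(segments))])
    low = factors < factor_threshold
    count = 0
    run_dur = 0.0
    for is_low, seg in zip(np.append(low, False), segments + [None]):
        if is_low and seg is not None:
            run_dur += seg.duration
        else:
            if run_dur >= min_duration:
                count += 1
            run_dur = 0.0
    return count


# ---------------------------------------------------------------------------
# Eye movements (REM / SEM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _HalfWave:
    start: int
    stop: int
    sign: float
    amplitude: float
    max_slope: float  # uV per ms


def _half_waves(x: np.ndarray, fs: float, min_amplitude: float) -> list[_HalfWave]:
    out = []
    for seg in zero_crossing_segments(x, fs):
        a, b = seg.start_index, seg.start_index + int(round(seg.duration * fs))
        chunk = x[a:b]
        if seg.amplitude < min_amplitude or chunk.size < 2:
            continue
        slope = float(np.max(np.abs(np.diff(chunk)))) * fs / 1000.0
        out.append(_HalfWave(start=a, stop=b, sign=float(np.sign(chunk.sum())),
                             amplitude=seg.amplitude, max_slope=slope))
    return out


def detect_eye_movements(eog_left: SignalRecord, eog_right: SignalRecord,
                         grid: EpochGrid, min_amplitude: float = 25.0,
                         rem_max_duration: float = 0.5,
                         rem_min_slope: float = 1.0,
                         band: tuple[float, float] = (0.3, 10.0)
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch counts of rapid and slow conjugate eye movements.

    A candidate event is a half-wave (between baseline crossings of the
    band-passed EOG) of at least ``min_amplitude`` uV on one channel with an
    overlapping, opposite-signed half-wave on the other channel (conjugacy —
    the eyes move together, so the two periorbital electrodes see mirrored
    deflections).  The initial deflection duration decides the class: under
    ``rem_max_duration`` s with a peak slope above ``rem_min_slope`` uV/ms it
    is a REM; over it, a SEM.
    """
    if (eog_left.sampling_rate != eog_right.sampling_rate
            or eog_left.samples.size != eog_right.samples.size):
        raise ValueError("EOG channels must share sampling rate and duration")
    fs = eog_left.sampling_rate
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xl = signal.sosfiltfilt(sos, eog_left.samples)
    xr = signal.sosfiltfilt(sos, eog_right.samples)
    hw_l = _half_waves(xl, fs, min_amplitude)
    hw_r = _half_waves(xr, fs, min_amplitude)

    n_rems = np.zeros(grid.n_epochs, dtype=np.intp)
    n_sems = np.zeros(grid.n_epochs, dtype=np.intp)
    used_r: set[int] = set()
    spe = int(round(grid.epoch_length * fs))
    for wl in hw_l:
        match = None
        for k, wr in enumerate(hw_r):
            if k in used_r or wr.sign == wl.sign:
                continue
            if wl.start < wr.stop and wr.start < wl.stop:  # temporal overlap
                match = k
                break
        if match is None:
            continue
        used_r.add(match)
        first = wl if wl.start <= hw_r[match].start else hw_r[match]
        duration = (first.stop - first.start) / fs
        epoch = min(first.start // spe, grid.n_epochs - 1)
        if duration < rem_max_duration and first.max_slope > rem_min_slope:
            n_rems[epoch] += 1
        elif duration > rem_max_duration:
            n_sems[epoch] += 1
    return n_rems, n_sems


# ---------------------------------------------------------------------------
# Background EMG
# ---------------------------------------------------------------------------

def emg_background(emg_channels: list[SignalRecord], grid: EpochGrid,
                   mains_hz: float = 50.0, bandpass=(10.0, 100.0),
                   envelope_s: float = 0.05, opening_s: float = 0.5) -> np.ndarray:
    """Per-epoch background EMG, median-centred over the recording.

    Each channel is notch-filtered around the mains frequency, band-passed,
    rectified into a short (50 ms) envelope and morphologically opened (flat
    0.5-s structuring element) so brief intentional movements are removed
    and the muscle-tonus floor remains.  Channel-averaged epoch means are
    divided by the recording-wide median, so the median epoch sits at 1 and
    values above 1 flag elevated tonus (typical of wake).
    """
    if not emg_channels:
        raise ValueError("no EMG signal")
    per_chan = []
    for ch in emg_channels:
        fs = ch.sampling_rate
        x = np.asarray(ch.samples, dtype=float)
        if mains_hz < 0.45 * fs:
            sos = signal.butter(4, (mains_hz - 1.0, mains_hz + 1.0),
                                btype="bandstop", fs=fs, output="sos")
            x = signal.sosfiltfilt(sos, x)
        hi = min(bandpass[1], 0.45 * fs)
        sos = signal.butter(4, (bandpass[0], hi), btype="bandpass", fs=fs,
                            output="sos")
        x = np.abs(signal.sosfiltfilt(sos, x))
        x = ndimage.uniform_filter1d(x, size=max(1, int(round(envelope_s * fs))))
        x = ndimage.grey_opening(x, size=max(2, int(round(opening_s * fs))))
        wins = partition_epochs(SignalRecord(ch.label, fs, x), grid)
        per_chan.append(wins.mean(axis=1))
    track = np.mean(per_chan, axis=0)
    med = np.median(track)
    if med <= 0:
        raise ValueError("no EMG signal")
    return track / med


# ---------------------------------------------------------------------------
# Heart rate, position, SaO2, snores, densities
# ---------------------------------------------------------------------------

def heart_rate_features(hr_per_epoch) -> tuple[np.ndarray, np.ndarray]:
    """Mid-rank quantile of each epoch's heart rate within the recording,
    and the epoch-to-epoch rate change (0 for the first epoch)."""
    hr = np.asarray(hr_per_epoch, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rates must be positive")
    quantile = (rankdata(hr, method="average") - 0.5) / hr.size
    change = np.diff(hr, prepend=hr[:1])
    return quantile, change


def heart_rate_from_ecg(ecg: SignalRecord, grid: EpochGrid) -> np.ndarray:
    """Per-epoch heart rate (bpm) from a raw ECG via simple R-peak counting.

    A convenience path only; per-epoch heart-rate input is preferred.
    """
    fs = ecg.sampling_rate
    sos = signal.butter(2, (5.0, min(15.0, 0.45 * fs)), btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, ecg.samples) ** 2
    thr = 4.0 * np.median(x) + 1e-12
    peaks, _ = signal.find_peaks(x, height=thr, distance=int(0.3 * fs))
    counts = np.histogram(peaks / fs, bins=np.arange(
        grid.start_offset, grid.duration + grid.epoch_length,
        grid.epoch_length))[0][: grid.n_epochs]
    return counts * 60.0 / grid.epoch_length


def position_change_flags(position_labels) -> np.ndarray:
    """1 where the body-position label differs from the previous epoch."""
    labels = list(position_labels)
    unknown = set(labels) - set(POSITION_LABELS)
    if unknown:
        raise ValueError(f"unknown position label(s): {sorted(unknown)}")
    flags = np.zeros(len(labels), dtype=np.intp)
    for t in range(1, len(labels)):
        flags[t] = int(labels[t] != labels[t - 1])
    return flags


def sao2_stats(sao2_epoch, dropout_below: float = 50.0) -> tuple[float, float]:
    """Mean and population variance of oxygen saturation in one epoch.

    Samples below ``dropout_below`` % are treated as sensor dropout and
    excluded; if nothing remains, ``(nan, nan)`` is returned so the emission
    layer can flag the group as missing.
    """
    x = np.asarray(sao2_epoch, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("SaO2 values must be in [0, 100]")
    keep = x[x >= dropout_below]
    if keep.size == 0:
        return float("nan"), float("nan")
    return float(keep.mean()), float(keep.var())


@dataclass(frozen=True)
class PsgDensities:
    """Recording-level mean event counts per epoch."""

    spindle_density: float
    rem_density: float
    sem_density: float


def compute_densities(spindle_counts, rem_counts, sem_counts) -> PsgDensities:
    """Average each per-epoch count track over the whole recording."""
    return PsgDensities(
        spindle_density=float(np.mean(spindle_counts)),
        rem_density=float(np.mean(rem_counts)),
        sem_density=float(np.mean(sem_counts)))


def count_snores(grid: EpochGrid, snore_events=None,
                 microphone: SignalRecord | None = None,
                 envelope_s: float = 0.05,
                 min_dur: float = 0.1, max_dur: float = 2.0) -> np.ndarray:
    """Per-epoch snore counts from an event list or, failing that, a
    microphone signal (supra-threshold envelope bursts of 0.1-2 s)."""
    if snore_events is None and microphone is None:
        raise ValueError("provide snore_events or a microphone signal")
    if snore_events is not None:
        times = np.asarray(snore_events, dtype=float)
    else:
        fs = microphone.sampling_rate
        env = ndimage.uniform_filter1d(np.abs(microphone.samples),
                                       size=max(1, int(envelope_s * fs)))
        thr = 3.0 * np.median(env)
        above = env > thr
        if thr <= 0 or not above.any():
            return np.zeros(grid.n_epochs, dtype=np.intp)
        times = []
        run_start = None
        for i, flag in enumerate(np.append(above, False)):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                dur = (i - run_start) / fs
                if min_dur <= dur <= max_dur:
                    times.append(run_start / fs)
                run_start = None
        times = np.asarray(times, dtype=float)
    bins = np.arange(grid.start_offset,
                     grid.start_offset + grid.duration + grid.epoch_length,
                     grid.epoch_length)[: grid.n_epochs + 1]
    return np.histogram(times, bins=bins)[0]


# ---------------------------------------------------------------------------
# Orchestration: signals -> feature table
# ---------------------------------------------------------------------------

def extract_features(signals: dict, grid: EpochGrid,
                     orp_model: OrpLikeliness | None = None,
                     hr_per_epoch=None, position_per_epoch=None,
                     snore_events=None,
                     spindle_factor_threshold: float = 1.0) -> pd.DataFrame:
    """Build the full per-epoch feature table from raw channels.

    ``signals`` maps roles (``EEG``, ``EOG_L``, ``EOG_R``, ``EMG`` — a list —
    ``SAO2``, ``MIC``) to :class:`SignalRecord`.  Missing optional roles
    yield NaN columns, which the emission layer later maps to uninformative
    (uniform) emissions.  Densities are appended as constant columns.
    """
    n = grid.n_epochs
    df = pd.DataFrame(index=np.arange(n), columns=list(FEATURE_COLUMNS),
                      dtype=float)

    if "EEG" in signals:
        eeg = signals["EEG"]
        wins = partition_epochs(eeg, grid)
        df["n_spindles"] = [detect_spindles(w, eeg.sampling_rate,
                                            spindle_factor_threshold)
                            for w in wins]
        if orp_model is not None:
            powers = windowed_band_powers(
                eeg.samples[: int(grid.duration * eeg.sampling_rate)],
                eeg.sampling_rate, orp_model.window_s)
            scores = orp_model.epoch_scores(powers,
                                            epoch_length=grid.epoch_length)[:n]
            for i, s in enumerate(STAGES):
                df[f"orp_{s}"] = scores[:, i]

    if "EOG_L" in signals and "EOG_R" in signals:
        rems, sems = detect_eye_movements(signals["EOG_L"], signals["EOG_R"], grid)
        df["n_rems"], df["n_sems"] = rems, sems

    if signals.get("EMG"):
        df["emg_background"] = emg_background(signals["EMG"], grid)

    if hr_per_epoch is not None:
        q, c = heart_rate_features(hr_per_epoch)
        df["hr_quantile"], df["hr_change"] = q[:n], c[:n]
    elif "ECG" in signals:
        hr = heart_rate_from_ecg(signals["ECG"], grid)
        if np.all(hr > 0):
            q, c = heart_rate_features(hr)
            df["hr_quantile"], df["hr_change"] = q, c

    if "SAO2" in signals:
        sao2 = signals["SAO2"]
        stats = [sao2_stats(w) for w in partition_epochs(sao2, grid)]
        df["sao2_mean"] = [m for m, _ in stats]
        df["sao2_var"] = [v for _, v in stats]

    if position_per_epoch is not None:
        df["position_change"] = position_change_flags(position_per_epoch)[:n]

    if snore_events is not None or "MIC" in signals:
        df["n_snores"] = count_snores(grid, snore_events=snore_events,
                                      microphone=signals.get("MIC"))

    dens = compute_densities(df["n_spindles"].fillna(0),
                             df["n_rems"].fillna(0), df["n_sems"].fillna(0))
    df["spindle_density"] = dens.spindle_density
    df["rem_density"] = dens.rem_density
    df["sem_density"] = dens.sem_density
    return df
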