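"""Waveform preparation: fiducial detection, PTT, beat averaging, quality flags.

Each 10-s window of a record is reduced to one normalized averaged beat per
waveform (unit duration, unit amplitude), plus the window's pulse transit
time (R peak to steepest pulse upstroke, median over beats) and heart rate.
R and T waves are discriminated by the 0.7 threshold on the baseline-
corrected, max-normalized amplitude: the supra-threshold peak of each beat
is the R wave, the first sub-threshold positive peak after it the T wave.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter

from .config import RunConfig
from .errors import FlatSignalError, InsufficientBeatsError
from .types import AveragedBeat, BeatWindowSummary, RawRecord


def rolling_baseline(x: np.ndarray, sampling_rate: float,
                     window_s: float = 0.6) -> np.ndarray:
    """Rolling-median baseline, computed on a decimated copy for speed."""
    dec = max(1, int(sampling_rate // 128))
    xd = x[::dec]
    k = max(3, int(round(window_s * sampling_rate / dec)) | 1)
    bd = median_filter(xd, size=k, mode="nearest")
    idx = np.arange(len(xd)) * dec
    return np.interp(np.arange(len(x)), idx, bd)


def _bandpass(x: np.ndarray, sampling_rate: float,
              band: tuple[float, float]) -> np.ndarray:
    sos = sps.butter(2, band, btype="bandpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _normalize_from_baseline(x: np.ndarray, sampling_rate: float,
                             window_s: float) -> np.ndarray | None:
    """Baseline-corrected amplitude scaled so the largest excursion is 1.

    Invariant to positive affine rescaling of the input. Returns None for a
    flat (or purely non-positive) signal.
    """
    z = x - rolling_baseline(x, sampling_rate, window_s)
    m = z.max()
    if m <= 0 or not np.isfinite(m):
        return None
    return z / m


def detect_r_and_t_peaks(ecg: np.ndarray, sampling_rate: float,
                         config: RunConfig | None = None
                         ) -> tuple[np.ndarray, np.ndarray, set]:
    """Detect R peaks (normalized amplitude > 0.7) and the following T peaks.

    Returns (r_indices, t_indices, quality_flags); an undetectable signal
    yields empty arrays and the ``unclear_crest`` flag.
    """
    config = config or RunConfig()
    flags: set[str] = set()
    if len(ecg) < 2 * sampling_rate:
        raise ValueError("need at least 2 s of signal")
    filt = _bandpass(ecg, sampling_rate, config.prefilter_band_hz)
    z = _normalize_from_baseline(filt, sampling_rate, config.baseline_window_s)
    if z is None:
        return np.array([], int), np.array([], int), {"unclear_crest"}
    thr = config.rt_threshold
    min_dist = int(0.25 * sampling_rate)
    r_idx, _ = sps.find_peaks(z, height=thr, distance=min_dist)
    if len(r_idx) == 0:
        return np.array([], int), np.array([], int), {"unclear_crest"}
    t_idx = []
    bounds = np.append(r_idx, len(z))
    for i, r in enumerate(r_idx):
        lo = r + int(0.08 * sampling_rate)
        hi = bounds[i + 1] - int(0.05 * sampling_rate)
        if hi <= lo:
            continue
        pk, props = sps.find_peaks(z[lo:hi], height=(0.05, thr))
        if len(pk):
            t_idx.append(lo + pk[0])
    return r_idx.astype(int), np.array(t_idx, int), flags


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    width = max(3, width | 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_pulse_onsets(pulse: np.ndarray, sampling_rate: float,
                        config: RunConfig | None = None
                        ) -> tuple[np.ndarray, set]:
    """One onset per cardiac cycle: the maximum of the first derivative on
    the rising edge preceding each systolic peak."""
    config = config or RunConfig()
    if len(pulse) < 2 * sampling_rate:
        raise ValueError("need at least 2 s of signal")
    filt = _bandpass(pulse, sampling_rate, config.prefilter_band_hz)
    z = _normalize_from_baseline(filt, sampling_rate, config.baseline_window_s)
    if z is None:
        return np.array([], int), {"unclear_crest"}
    peaks, _ = sps.find_peaks(z, height=config.rt_threshold,
                              distance=int(0.25 * sampling_rate))
    if len(peaks) == 0:
        return np.array([], int), {"unclear_crest"}
    # The slope is computed on a low-pass-only copy: the high-pass half of
    # the detection band reshapes the pulse complex (more so the larger the
    # reflected wave) and biases the steepest-upstroke point, while a plain
    # zero-phase low-pass kills sample noise without moving it.
    sos = sps.butter(2, 24.0, btype="lowpass", fs=sampling_rate, output="sos")
    slope = np.gradient(_smooth(sps.sosfiltfilt(sos, pulse),
                                int(0.009 * sampling_rate)))
    onsets = []
    for p in peaks:
        lo = max(0, p - int(0.25 * sampling_rate))
        if p <= lo:
            continue
        onsets.append(lo + int(np.argmax(slope[lo:p])))
    flags = set() if len(onsets) > 1 else {"unclear_crest"}
    return np.array(onsets, int), flags


def beat_transits(r_peak_indices: np.ndarray, pulse_onset_indices: np.ndarray,
                  sampling_rate: float) -> np.ndarray:
    """Per-beat transit times in ms: first onset after each R, before the
    next R; unmatched beats are skipped."""
    r = np.asarray(r_peak_indices)
    onsets = np.sort(np.asarray(pulse_onset_indices))
    transits = []
    bounds = np.append(r, np.iinfo(np.int64).max)
    for i, ri in enumerate(r):
        j = np.searchsorted(onsets, ri, side="left")
        if j < len(onsets) and onsets[j] < bounds[i + 1]:
            transits.append(onsets[j] - ri)
    return np.asarray(transits, dtype=float) / sampling_rate * 1000.0


def compute_ptt(r_peak_indices: np.ndarray, pulse_onset_indices: np.ndarray,
                sampling_rate: float) -> float:
    """Window PTT in ms: median over the matched per-beat transits.

    Fewer than three matched pairs raises :class:`InsufficientBeatsError`.
    """
    transits = beat_transits(r_peak_indices, pulse_onset_indices,
                             sampling_rate)
    if len(transits) < 3:
        raise InsufficientBeatsError(
            f"only {len(transits)} matched R-onset pairs (need >= 3)")
    return float(np.median(transits))


def average_beats(signal: np.ndarray, anchor_indices: np.ndarray,
                  sampling_rate: float, window_s: float = 10.0,
                  out_length: int = 1024, waveform_kind: str = "ecg",
                  window_start_s: float = 0.0) -> AveragedBeat:
    """Average anchored beats of one window into a single normalized beat.

    Each anchor-to-anchor segment is resampled to ``out_length`` points
    (time normalization to a 1-s axis), segments are averaged pointwise,
    and the result is min-max normalized to [0, 1].
    """
    lo = int(window_start_s * sampling_rate)
    hi = int((window_start_s + window_s) * sampling_rate)
    anchors = np.asarray(anchor_indices)
    anchors = anchors[(anchors >= lo) & (anchors < hi)]
    if len(anchors) < 3:
        raise InsufficientBeatsError(
            f"window holds {len(anchors)} anchored beats (need >= 3)")
    grid = np.arange(out_length) / out_length
    acc = np.zeros(out_length)
    nseg = 0
    for a, b in zip(anchors[:-1], anchors[1:]):
        seg = signal[a:b + 1]
        src = np.linspace(0.0, 1.0, len(seg))
        acc += np.interp(grid, src, seg)
        nseg += 1
    avg = acc / nseg
    rng = avg.max() - avg.min()
    if rng <= 0 or not np.isfinite(rng):
        raise FlatSignalError("averaged beat has zero amplitude range")
    samples = (avg - avg.min()) / rng
    return AveragedBeat(waveform_kind=waveform_kind, samples=samples,
                        source_window=(window_start_s, window_start_s + window_s),
                        n_beats_averaged=nseg)


def _powerline_ratio(x: np.ndarray, sampling_rate: float, line_hz: float) -> float:
    f, pxx = sps.welch(x, fs=sampling_rate, nperseg=min(len(x), 4096))
    band = (f >= line_hz - 1.5) & (f <= line_hz + 1.5)
    total = pxx[(f >= 1.0)].sum()
    if total <= 0:
        return 0.0
    return float(pxx[band].sum() / total)


def assess_quality(record: RawRecord, config: RunConfig | None = None,
                   summary: "BeatWindowSummary | None" = None) -> set:
    """Advisory quality flags; exclusion decisions belong to the protocol layer.

    low_amplitude    peak-to-peak below a configured fraction of full scale
    unclear_crest    fewer than 3 beats detectable per 10-s window
    powerline_noise  mains-band power exceeds a configured share of total
    wavelet_error    degenerate/non-finite waveform (transform cannot succeed)
    """
    config = config or RunConfig()
    flags: set[str] = set()
    fs = record.sampling_rate
    for x in (record.ecg, record.pulse):
        if np.ptp(x) < config.low_amplitude_frac * config.full_scale:
            flags.add("low_amplitude")
        if not np.all(np.isfinite(x)) or np.ptp(x) == 0:
            flags.add("wavelet_error")
        if _powerline_ratio(x, fs, config.powerline_hz) > config.powerline_ratio:
            flags.add("powerline_noise")
    if summary is not None:
        flags |= {f for f in summary.quality_flags if f != "powerline_noise"}
        beats_per_10s = len(summary.r_peak_indices) * 10.0 / record.duration
        if beats_per_10s < 3:
            flags.add("unclear_crest")
    else:
        try:
            r_idx, _, det_flags = detect_r_and_t_peaks(record.ecg, fs, config)
            if len(r_idx) * 10.0 / record.duration < 3:
                flags.add("unclear_crest")
            flags |= det_flags
        except ValueError:
            flags.add("unclear_crest")
        onsets, on_flags = detect_pulse_onsets(record.pulse, fs, config)
        if len(onsets) * 10.0 / record.duration < 3:
            flags.add("unclear_crest")
    return flags


def summarize_window(record: RawRecord, config: RunConfig | None = None,
                     window_start_s: float = 0.0
                     ) -> tuple[BeatWindowSummary, AveragedBeat, AveragedBeat]:
    """Run full preparation on one window of a record.

    Returns the window summary plus the averaged ECG beat (R-to-R anchors)
    and averaged pulse beat (onset-to-onset anchors).
    """
    config = config or RunConfig()
    fs = record.sampling_rate
    lo = int(window_start_s * fs)
    hi = int((window_start_s + config.beat_window_s) * fs)
    ecg_w = record.ecg[lo:hi]
    pulse_w = record.pulse[lo:hi]

    r_idx, t_idx, ecg_flags = detect_r_and_t_peaks(ecg_w, fs, config)
    onsets, pulse_flags = detect_pulse_onsets(pulse_w, fs, config)
    flags = set(ecg_flags) | set(pulse_flags)
    if len(r_idx) < 3 or len(onsets) < 3:
        flags.add("unclear_crest")
        raise InsufficientBeatsError(
            f"window yields {len(r_idx)} R peaks / {len(onsets)} onsets")

    transits = beat_transits(r_idx, onsets, fs)
    ptt = compute_ptt(r_idx, onsets, fs)
    ptt_cv = float(np.std(transits) / np.mean(transits)) \
        if np.mean(transits) > 0 else 0.0
    rr_s = float(np.median(np.diff(r_idx))) / fs
    hr = 60.0 / rr_s

    # baseline-corrected (unnormalized) R amplitude, in full-scale units
    z = ecg_w - rolling_baseline(ecg_w, fs, config.baseline_window_s)
    ecg_peak = float(np.median(z[r_idx]) / config.full_scale)

    summary = BeatWindowSummary(
        ptt=ptt, heart_rate=hr, r_peak_indices=r_idx + lo,
        t_peak_indices=t_idx + lo, pulse_onset_indices=onsets + lo,
        ecg_peak_amplitude=ecg_peak, quality_flags=flags, ptt_cv=ptt_cv)
    ecg_beat = average_beats(record.ecg, r_idx + lo, fs, config.beat_window_s,
                             config.out_length, "ecg", window_start_s)
    pulse_beat = average_beats(record.pulse, onsets + lo, fs,
                               config.beat_window_s, config.out_length,
                               "pulse", window_start_s)
    return summary, ecg_beat, pulse_beat
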