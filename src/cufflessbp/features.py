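"""Wavelet-grid and scalar feature extraction from averaged beats.

The normalized 1-s beat is analysed with a complex Morlet continuous
wavelet transform over 64 log-spaced scales spanning pseudo-frequencies
1-128 Hz on the normalized axis. |Coefficients| are pooled by mean into a
20 (time) x 8 (frequency) grid of equal-partition cells per waveform, so
an ECG + pulse pair contributes 20 x 8 x 2 = 320 wavelet features. The
scalar block adds PTT, 1/PTT, heart rate, demographics-derived values, the
ECG peak amplitude and the a-e extrema of the second-derivative pulse wave
(SDPPG), the classical vascular-stiffness fiducials.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .config import RunConfig
from .errors import ExtremaError, MissingFeatureError, WaveletError
from .types import AveragedBeat, BeatWindowSummary, WaveletGrid

SDPPG_POINTS = ("a", "b", "c", "d", "e")

#: Scalar feature names, in the fixed serialization order.
SCALAR_FEATURES = ("ptt_ms", "inv_ptt", "hr_bpm", "weight_kg", "sqrt_weight",
                   "height_cm", "bmi", "age_y", "ecg_peak",
                   "sdppg_a", "sdppg_b", "sdppg_c", "sdppg_d", "sdppg_e")


def wavelet_feature_names(config: RunConfig | None = None) -> list[str]:
    """Stable header for the 320 grid cells: ECG grid then pulse grid,
    time-major (w_ecg_t01_f1 ... w_pls_t20_f8)."""
    config = config or RunConfig()
    names = []
    for kind in ("ecg", "pls"):
        for ti in range(1, config.time_bands + 1):
            for fi in range(1, config.freq_bands + 1):
                names.append(f"w_{kind}_t{ti:02d}_f{fi}")
    return names


def feature_names(config: RunConfig | None = None) -> list[str]:
    return wavelet_feature_names(config) + list(SCALAR_FEATURES)


def cwt_scales(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """(pseudo-frequencies ascending, matching scales) for the ladder."""
    freqs = np.geomspace(config.freq_min_hz, config.freq_max_hz, config.n_scales)
    dt = 1.0 / config.out_length          # normalized beat spans 1 s
    scales = pywt.frequency2scale(config.wavelet, freqs * dt)
    return freqs, scales


def cwt_grid(beat: AveragedBeat, config: RunConfig | None = None) -> WaveletGrid:
    """Mean |CWT coefficient| in each of the 20 x 8 equal-partition cells.

    The beat is symmetrically padded before the transform and the padding
    region is excluded from pooling, so cell time supports are exactly the
    [k/20, (k+1)/20) intervals of the normalized axis.
    """
    config = config or RunConfig()
    x = np.asarray(beat.samples, dtype=float)
    n = len(x)
    _, scales = cwt_scales(config)
    dt = 1.0 / config.out_length
    pad = n // 2
    xp = np.pad(x, pad, mode="symmetric")
    coef, _ = pywt.cwt(xp, scales, config.wavelet, sampling_period=dt,
                       method="fft")
    mag = np.abs(coef[:, pad:pad + n])            # (n_scales, n), low->high freq
    if not np.all(np.isfinite(mag)):
        raise WaveletError(f"non-finite CWT output for {beat.waveform_kind} beat")
    per_band = config.n_scales // config.freq_bands
    tb, fb = config.time_bands, config.freq_bands
    t_edges = (np.arange(tb + 1) * n) // tb
    cells = np.empty((tb, fb))
    for fi in range(fb):
        rows = mag[fi * per_band:(fi + 1) * per_band]
        for ti in range(tb):
            cells[ti, fi] = rows[:, t_edges[ti]:t_edges[ti + 1]].mean()
    return WaveletGrid(waveform_kind=beat.waveform_kind, cells=cells)


def sdppg_points(pulse_beat: AveragedBeat, smooth_width: int = 5,
                 prominence_frac: float = 0.02) -> dict:
    """a-e amplitudes of the second-derivative pulse waveform.

    The beat is smoothed by a short moving average, twice differenced, and
    the alternating extrema sequence is read off: a = first prominent
    maximum, b = following minimum, then c, d, e. Later extrema that do not
    exist are reported as None, not invented.
    """
    x = np.asarray(pulse_beat.samples, dtype=float)
    kernel = np.ones(smooth_width) / smooth_width
    xs = np.convolve(x, kernel, mode="same")
    d2 = np.diff(xs, 2)
    span = d2.max() - d2.min()
    if span <= 0:
        raise ExtremaError("second derivative has no extrema (flat input)")
    prom = prominence_frac * span
    maxima, _ = sps.find_peaks(d2, prominence=prom)
    minima, _ = sps.find_peaks(-d2, prominence=prom)
    ext = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    # drop leading minima so the sequence starts at a (a maximum)
    while ext and ext[0][1] == "min":
        ext.pop(0)
    if len(ext) < 2:
        raise ExtremaError(f"only {len(ext)} usable extrema in the SDPPG")
    out: dict[str, float | None] = {k: None for k in SDPPG_POINTS}
    want = "max"
    k = 0
    for idx, kind in ext:
        if kind != want or k >= len(SDPPG_POINTS):
            continue
        out[SDPPG_POINTS[k]] = float(d2[idx])
        k += 1
        want = "min" if want == "max" else "max"
    return out


def assemble_features(summary: BeatWindowSummary, ecg_beat: AveragedBeat,
                      pulse_beat: AveragedBeat, demographics: dict,
                      config: RunConfig | None = None) -> dict:
    """One measurement's full feature vector as an ordered name->value dict.

    ``demographics`` must provide age (years), weight (kg) and height (cm);
    a missing field raises an error naming it. SDPPG points that could not
    be located are imputed as 0.0 (flat curvature).
    """
    config = config or RunConfig()
    for fieldname in ("age", "weight", "height"):
        if fieldname not in demographics or demographics[fieldname] is None:
            raise MissingFeatureError(f"missing demographic field: {fieldname}")
    grids = [cwt_grid(ecg_beat, config), cwt_grid(pulse_beat, config)]
    values: dict[str, float] = {}
    for name, val in zip(wavelet_feature_names(config),
                         np.concatenate([g.cells.ravel() for g in grids])):
        values[name] = float(val)
    try:
        sd = sdppg_points(pulse_beat)
    except ExtremaError:
        sd = {k: None for k in SDPPG_POINTS}
    weight = float(demographics["weight"])
    height = float(demographics["height"])
    values.update({
        "ptt_ms": summary.ptt,
        "inv_ptt": 1.0 / summary.ptt,
        "hr_bpm": summary.heart_rate,
        "weight_kg": weight,
        "sqrt_weight": float(np.sqrt(weight)),
        "height_cm": height,
        "bmi": weight / (height / 100.0) ** 2,
        "age_y": float(demographics["age"]),
        "ecg_peak": summary.ecg_peak_amplitude,
    })
    for k in SDPPG_POINTS:
        values[f"sdppg_{k}"] = float(sd[k]) if sd[k] is not None else 0.0
    return values
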