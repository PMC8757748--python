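"""Domain containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Waveform quality / artifact labels shared by the simulator and the
#: quality-assessment stage.
ARTIFACT_LABELS = ("low_amplitude", "unclear_crest", "powerline_noise",
                   "wavelet_error_trigger")
QUALITY_FLAGS = ("low_amplitude", "unclear_crest", "powerline_noise",
                 "wavelet_error")


@dataclass
class ParticipantProfile:
    """One synthetic participant with hidden ground-truth vascular parameters.

    ``ptt_coefficient`` is the constant c (mmHg*ms) of the participant's
    SBP = c / PTT law; the five stiffness classes occupy disjoint, ordered
    coefficient ranges (class 1 highest).
    """

    participant_id: str
    age: float                 # years
    sex: str                   # "female" | "male"
    weight: float              # kg
    height: float              # cm
    stiffness_class: int       # 1..5, hidden truth
    bp_setpoint_sbp: float     # mmHg
    bp_setpoint_dbp: float     # mmHg
    ptt_coefficient: float     # mmHg*ms, hidden truth
    dbp_ratio: float = 0.65    # DBP ~= ratio * SBP
    dia_amplitude: float = 0.35  # diastolic (reflected) wave amplitude, relative
    dia_delay_s: float = 0.24    # diastolic wave delay after the systolic peak

    def __post_init__(self) -> None:
        if self.stiffness_class not in (1, 2, 3, 4, 5):
            raise ValueError("stiffness_class must be in 1..5")
        if not self.bp_setpoint_sbp > self.bp_setpoint_dbp > 0:
            raise ValueError("require bp_setpoint_sbp > bp_setpoint_dbp > 0")


@dataclass
class RawRecord:
    """Paired ECG + pulse sample arrays with sampling metadata.

    ``truth`` (simulator output only) carries the hidden per-beat ground
    truth: R-peak sample indices, pulse-onset sample indices, the embedded
    PTT in ms and the session BP.
    """

    ecg: np.ndarray
    pulse: np.ndarray
    sampling_rate: float = 1024.0
    resolution_bits: int = 12
    duration: float = 0.0
    artifact_labels: frozenset = frozenset()
    clipped: bool = False
    truth: dict | None = None

    def __post_init__(self) -> None:
        if len(self.ecg) != len(self.pulse):
            raise ValueError("ecg and pulse must have equal length")


@dataclass
class ReferenceMeasurement:
    """Dual-observer auscultatory reading (all raw values even mmHg)."""

    obs1_sbp: int
    obs1_dbp: int
    obs2_sbp: int
    obs2_dbp: int
    merged_sbp: float | None = None
    merged_dbp: float | None = None
    valid: bool | None = None
    reason: str | None = None


@dataclass
class SessionRecord:
    """One measurement session: reference - device record - reference."""

    participant_id: str
    session_id: str
    ref_before: ReferenceMeasurement
    device_record: RawRecord
    ref_after: ReferenceMeasurement
    true_sbp: float | None = None
    true_dbp: float | None = None
    true_ptt: float | None = None   # ms
    true_hr: float | None = None    # bpm


@dataclass
class AveragedBeat:
    """One representative beat on a normalized [0, 1) s time axis.

    After min-max normalization min(samples) == 0 and max(samples) == 1.
    """

    waveform_kind: str          # "ecg" | "pulse"
    samples: np.ndarray
    source_window: tuple        # (start_s, end_s)
    n_beats_averaged: int


@dataclass
class BeatWindowSummary:
    """Per-window fiducials and scalars from waveform preparation."""

    ptt: float                  # ms
    heart_rate: float           # bpm
    r_peak_indices: np.ndarray
    t_peak_indices: np.ndarray
    pulse_onset_indices: np.ndarray
    ecg_peak_amplitude: float   # baseline-corrected R height / full scale
    quality_flags: set = field(default_factory=set)
    ptt_cv: float = 0.0         # within-window PTT coefficient of variation


@dataclass
class WaveletGrid:
    """20 x 8 grid of mean |CWT coefficient| per cell for one waveform.

    Rows index the 20 equal time bands (from the start of the normalized
    1-s axis), columns the 8 frequency bands (from the low end of the
    scale ladder).
    """

    waveform_kind: str
    cells: np.ndarray           # shape (time_bands, freq_bands), all >= 0


@dataclass
class GroupBoundaries:
    """Coefficients of the four curved borders SBP = c / PTT, c1 > c2 > c3 > c4."""

    c1: float
    c2: float
    c3: float
    c4: float

    def __post_init__(self) -> None:
        cs = (self.c1, self.c2, self.c3, self.c4)
        if not all(c > 0 for c in cs):
            raise ValueError("border coefficients must be positive")
        if not (self.c1 > self.c2 > self.c3 > self.c4):
            raise ValueError("borders must satisfy c1 > c2 > c3 > c4")

    def as_array(self) -> np.ndarray:
        return np.array([self.c4, self.c3, self.c2, self.c1])


@dataclass
class GroupRegressor:
    """Per-group linear BP model on forward-selected features."""

    group_label: int
    target: str                       # "sbp" | "dbp"
    selected_features: list
    coefficients: np.ndarray          # aligned with selected_features
    intercept: float
    pooled_fallback: bool = False     # True when the group was below min_group_n

    def predict(self, features: "np.ndarray | dict") -> float:
        if isinstance(features, dict):
            x = np.array([features[name] for name in self.selected_features],
                         dtype=float)
        else:
            x = np.asarray(features, dtype=float)
        return float(self.intercept + x @ self.coefficients)


@dataclass
class BPEstimate:
    sbp_hat: float
    dbp_hat: float
    group_used: int
    clamped: bool = False       # dbp_hat pulled below sbp_hat post-hoc
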