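"""Run configuration: the fixed constants of the estimation pipeline.

The defaults are the method's published operating point: 1024 Hz / 12-bit
acquisition, 10-s averaging windows with beats rescaled to a 1-s axis,
a 20 (time) x 8 (frequency) wavelet grid per waveform (320 features over
ECG + pulse), a 35-member bagged SVM group classifier, five BP groups at
ratio 1:1:3:3:2, and 10-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    # acquisition
    sampling_rate: float = 1024.0      # Hz
    resolution_bits: int = 12
    full_scale: float = 4.0            # quantizer span in signal units (+-2)
    # waveform preparation
    beat_window_s: float = 10.0        # averaging window
    out_length: int = 1024             # samples of the normalized 1-s beat
    baseline_window_s: float = 0.6     # rolling-median baseline for the 0.7 threshold
    rt_threshold: float = 0.7          # R/T discrimination on normalized amplitude
    prefilter_band_hz: tuple = (0.5, 40.0)   # detection-only band-pass
    # quality flags
    low_amplitude_frac: float = 0.05   # p2p below this fraction of full scale
    powerline_hz: float = 50.0
    powerline_ratio: float = 0.2       # band power ratio that raises the flag
    # wavelet grid
    wavelet: str = "cmor1.5-1.0"
    n_scales: int = 64
    freq_min_hz: float = 1.0           # pseudo-frequency range on the 1-s axis
    freq_max_hz: float = 128.0
    time_bands: int = 20
    freq_bands: int = 8
    # group model
    ensemble_size: int = 35
    svm_c: float = 1.0
    svm_c_grid: tuple = ()             # non-empty: pick C by 10-fold CV first
    svm_gamma: str = "scale"
    border_mode: str = "quantile"      # or "spacing"
    classifier_features: str = "all"   # or "scalar"
    # regression
    max_features: int = 24
    obs_per_feature: int = 10          # selection budget: n // this, capped above
    selection_tol: float = 0.5         # mmHg^2 inner-CV improvement to accept a feature
    inner_folds: int = 5
    selection_screen: int = 20         # candidates scored exactly per step
    min_group_n: int = 10
    # evaluation
    k_folds: int = 10
    fold_level: str = "participant"    # or "record"
    # exclusion thresholds (mmHg)
    observer_max_diff: float = 4.0
    prepost_max_sbp: float = 12.0
    prepost_max_dbp: float = 8.0
    min_sessions_per_participant: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.border_mode not in ("quantile", "spacing"):
            raise ConfigurationError(f"unknown border_mode: {self.border_mode!r}")
        if self.fold_level not in ("participant", "record"):
            raise ConfigurationError(f"unknown fold_level: {self.fold_level!r}")
        if self.classifier_features not in ("all", "scalar"):
            raise ConfigurationError(
                f"unknown classifier_features: {self.classifier_features!r}")
        if self.time_bands < 1 or self.freq_bands < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.n_scales % self.freq_bands != 0:
            raise ConfigurationError("n_scales must be a multiple of freq_bands")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prefilter_band_hz"] = list(d["prefilter_band_hz"])
        d["svm_c_grid"] = list(d["svm_c_grid"])
        return d

    def hash(self) -> str:
        """Stable digest of the fully-resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name, defaults filled."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    unknown = sorted(set(raw) - _FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("prefilter_band_hz", "svm_c_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
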