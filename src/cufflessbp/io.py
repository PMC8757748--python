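"""Readers/writers and model persistence.

CSV is the canonical interchange format (UTF-8, "." decimal): one
two-column signal file per session with header ``time_s,ecg,pulse``, a
cohort metadata CSV with one row per session per reference phase, and an
optional hidden-truth CSV. Trained pipelines persist as a joblib archive
with a versioned schema and a config hash that is checked on load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import IntegrityError, MissingChannelError, RateMismatchError
from .regression import PipelineModel
from .simulate import cohort_profiles
from .types import RawRecord

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

META_HEADER = ["participant_id", "session_id", "age", "sex", "weight_kg",
               "height_cm", "obs1_sbp", "obs1_dbp", "obs2_sbp", "obs2_dbp",
               "phase"]


def write_signals(record: RawRecord, path: str | Path) -> None:
    t = np.arange(len(record.ecg)) / record.sampling_rate
    pd.DataFrame({"time_s": t, "ecg": record.ecg, "pulse": record.pulse}
                 ).to_csv(path, index=False)


def read_signals(path: str | Path, config: RunConfig | None = None) -> RawRecord:
    """Read a session signal CSV; infers the sampling rate from the time
    column and checks it against the configuration."""
    config = config or RunConfig()
    df = pd.read_csv(path)
    for col in ("time_s", "ecg", "pulse"):
        if col not in df.columns:
            raise MissingChannelError(f"missing_channel: {col} not in {path}")
    if df[["ecg", "pulse"]].isna().any().any():
        raise MissingChannelError(f"ragged CSV (NaN samples) in {path}")
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(t))
    if abs(rate - config.sampling_rate) > 0.01 * config.sampling_rate:
        raise RateMismatchError(
            f"rate_mismatch: file at {rate:.1f} Hz, config expects "
            f"{config.sampling_rate:.1f} Hz")
    duration = len(t) / rate
    return RawRecord(ecg=df["ecg"].to_numpy(dtype=float),
                     pulse=df["pulse"].to_numpy(dtype=float),
                     sampling_rate=float(round(rate)),
                     resolution_bits=config.resolution_bits,
                     duration=duration)


def write_cohort(sessions, out_dir: str | Path, with_truth: bool = False,
                 fmt: str = "csv") -> Path:
    """Write signal files + metadata CSV (+ hidden-truth CSV on request)."""
    if fmt != "csv":
        raise ValueError(f"unsupported signal format {fmt!r}; only 'csv' "
                         "is available")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "signals").mkdir(exist_ok=True)
    profiles = cohort_profiles(sessions)
    meta_rows, truth_rows = [], []
    for s in sessions:
        p = profiles[s.participant_id]
        write_signals(s.device_record, out / "signals" / f"{s.session_id}.csv")
        for phase, ref in (("before", s.ref_before), ("after", s.ref_after)):
            meta_rows.append([s.participant_id, s.session_id, p.age, p.sex,
                              p.weight, p.height, ref.obs1_sbp, ref.obs1_dbp,
                              ref.obs2_sbp, ref.obs2_dbp, phase])
        truth_rows.append([s.participant_id, s.session_id, p.stiffness_class,
                           p.ptt_coefficient, s.true_sbp, s.true_dbp,
                           s.true_ptt, s.true_hr])
    pd.DataFrame(meta_rows, columns=META_HEADER).to_csv(
        out / "metadata.csv", index=False)
    if with_truth:
        pd.DataFrame(truth_rows, columns=[
            "participant_id", "session_id", "stiffness_class",
            "ptt_coefficient", "true_sbp", "true_dbp", "true_ptt_ms",
            "true_hr_bpm"]).to_csv(out / "truth.csv", index=False)
    return out


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model: PipelineModel, path: str | Path,
               config: RunConfig | None = None) -> None:
    config = config or RunConfig()
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": model.config_hash or config.hash(),
        "ensemble_size": config.ensemble_size,
        "boundaries": {"c1": model.boundaries.c1, "c2": model.boundaries.c2,
                       "c3": model.boundaries.c3, "c4": model.boundaries.c4},
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, config: RunConfig | None = None
               ) -> tuple[PipelineModel, bool]:
    """Load a model archive; returns (model, config_hash_matches).

    A member count differing from the archive's declared ensemble size is
    a schema violation and raises :class:`IntegrityError`; a config-hash
    mismatch only warns (flag returned False).
    """
    config = config or RunConfig()
    payload = joblib.load(path)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise IntegrityError("unsupported model schema version")
    model: PipelineModel = payload["model"]
    n_members = len(model.classifier.members)
    if n_members != payload["ensemble_size"]:
        raise IntegrityError(
            f"archive declares {payload['ensemble_size']} ensemble members "
            f"but holds {n_members}")
    hash_ok = payload["config_hash"] == config.hash()
    if not hash_ok:
        logger.warning("model config hash %s differs from run config %s",
                       payload["config_hash"], config.hash())
    return model, hash_ok
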