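"""End-to-end glue: cohort -> session feature table -> trained model -> report.

Training order inside a fold: fit the curved borders on the training
(PTT, reference SBP) pairs, label the training rows, train the bagged SVM
group classifier on the features (reference pressures are never features),
then fit per-group forward-selected linear models. Reference values only
ever label or supervise; held-out rows touch nothing during training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import CufflessBPError
from .features import SCALAR_FEATURES, assemble_features, feature_names
from .grouping import assign_group, fit_group_boundaries, train_group_classifier
from .prep import assess_quality, summarize_window
from .protocol import crossval_evaluate, screen_sessions
from .regression import PipelineModel, estimate_bp, fit_group_regressors
from .simulate import cohort_profiles

#: Session-table metadata columns (everything that is not a feature).
META_COLUMNS = ("participant_id", "session_id", "sex", "ref_sbp", "ref_dbp")


def prepare_sessions(sessions, config: RunConfig | None = None) -> pd.DataFrame:
    """Reduce raw sessions to one feature row each, plus screening inputs.

    Sessions whose waveforms defeat preparation keep their advisory flags
    and NaN features; the protocol screen decides exclusion downstream.
    """
    config = config or RunConfig()
    profiles = cohort_profiles(sessions)
    names = feature_names(config)
    rows = []
    for s in sessions:
        rec = s.device_record
        profile = profiles[s.participant_id]
        row: dict = {
            "participant_id": s.participant_id, "session_id": s.session_id,
            "sex": profile.sex,
            "obs1_sbp_before": s.ref_before.obs1_sbp,
            "obs1_dbp_before": s.ref_before.obs1_dbp,
            "obs2_sbp_before": s.ref_before.obs2_sbp,
            "obs2_dbp_before": s.ref_before.obs2_dbp,
            "obs1_sbp_after": s.ref_after.obs1_sbp,
            "obs1_dbp_after": s.ref_after.obs1_dbp,
            "obs2_sbp_after": s.ref_after.obs2_sbp,
            "obs2_dbp_after": s.ref_after.obs2_dbp,
        }
        flags: set = set()
        try:
            summary, ecg_beat, pulse_beat = summarize_window(rec, config)
            flags = assess_quality(rec, config, summary)
            row["ptt_cv"] = summary.ptt_cv
            values = assemble_features(
                summary, ecg_beat, pulse_beat,
                {"age": profile.age, "weight": profile.weight,
                 "height": profile.height}, config)
            row.update(values)
        except CufflessBPError:
            flags = assess_quality(rec, config)
            if not flags:
                flags.add("unclear_crest")
            row.update({n: np.nan for n in names})
        row["flags"] = frozenset(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def classifier_feature_names(config: RunConfig) -> list[str]:
    """Features the group classifier consumes (never reference SBP/DBP)."""
    if config.classifier_features == "scalar":
        return list(SCALAR_FEATURES)
    return feature_names(config)


def train_pipeline(train_table: pd.DataFrame, config: RunConfig | None = None,
                   rng_seed: int = 0) -> PipelineModel:
    """Fit boundaries, group classifier and per-group regressors."""
    config = config or RunConfig()
    names = feature_names(config)
    ss = np.random.SeedSequence(rng_seed)
    seed_clf, seed_reg = (int(s.generate_state(1)[0] % 2 ** 31)
                          for s in ss.spawn(2))
    ptt = train_table["ptt_ms"].to_numpy(dtype=float)
    ref_sbp = train_table["ref_sbp"].to_numpy(dtype=float)
    ref_dbp = train_table["ref_dbp"].to_numpy(dtype=float)
    boundaries = fit_group_boundaries(ptt, ref_sbp, config.border_mode)
    labels = assign_group(ptt, ref_sbp, boundaries)
    clf_names = classifier_feature_names(config)
    X_clf = train_table[clf_names].to_numpy(dtype=float)
    classifier = train_group_classifier(X_clf, labels, config, seed_clf,
                                        feature_names=clf_names)
    X = train_table[names].to_numpy(dtype=float)
    regressors = fit_group_regressors(X, ref_sbp, ref_dbp, labels, names,
                                      config, seed_reg)
    return PipelineModel(boundaries=boundaries, classifier=classifier,
                         regressors=regressors, feature_names=names,
                         config_hash=config.hash(),
                         classifier_feature_names=clf_names)


def predict_table(model: PipelineModel, table: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sbp_hat, dbp_hat, group) arrays for each row of a session table."""
    sbp_hat = np.empty(len(table))
    dbp_hat = np.empty(len(table))
    groups = np.empty(len(table), dtype=int)
    for j, (_, row) in enumerate(table.iterrows()):
        est = estimate_bp(model, row.to_dict())
        sbp_hat[j], dbp_hat[j], groups[j] = est.sbp_hat, est.dbp_hat, est.group_used
    return sbp_hat, dbp_hat, groups


def evaluate_cohort(sessions, config: RunConfig | None = None,
                    k: int | None = None, rng_seed: int = 0):
    """Prepare, screen and cross-validate a raw cohort; returns the
    evaluation report and the audit log of the screening pass."""
    config = config or RunConfig()
    prepared = prepare_sessions(sessions, config)
    retained, audit_log = screen_sessions(prepared, config)
    report = crossval_evaluate(retained, config, k, rng_seed)
    return report, audit_log
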