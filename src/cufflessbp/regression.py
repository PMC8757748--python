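"""Per-group linear BP estimation with greedy forward feature selection.

Each of the five groups gets its own ordinary-least-squares model per
target (SBP, DBP), built on features accepted one at a time: at every step
the candidate that most reduces inner-CV mean squared error joins the
model, and selection stops when no candidate improves the criterion by
more than the tolerance or the feature budget (24) is reached. To keep
selection tractable at the full 334-candidate width, each step scores
exactly (by inner CV) only the candidates most correlated with the current
residual; the pre-screen width is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .config import RunConfig
from .errors import MissingFeatureError
from .grouping import GroupClassifier, predict_group
from .types import BPEstimate, GroupBoundaries, GroupRegressor

logger = logging.getLogger(__name__)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of y ~ [1, X]; returns (p+1,) with
    intercept first."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _cv_mse(X: np.ndarray, y: np.ndarray, folds) -> float:
    errs = []
    for tr, va in folds:
        beta = _ols(X[tr], y[tr])
        pred = beta[0] + X[va] @ beta[1:]
        errs.append(np.mean((y[va] - pred) ** 2))
    return float(np.mean(errs))


def forward_select(X: np.ndarray, y: np.ndarray, candidates: list[str],
                   config: RunConfig | None = None, rng_seed: int = 0
                   ) -> list[str]:
    """Greedy forward selection by inner-CV MSE; deterministic given the seed.

    Returns the ordered list of accepted feature names (empty for a
    constant target: nothing explains variance).
    """
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < config.inner_folds + 2:
        raise ValueError(f"too few samples for selection: {n}")
    if np.ptp(y) == 0:
        return []
    name_to_col = {name: j for j, name in enumerate(candidates)}
    # constant columns can never help
    usable = [c for c in candidates if np.ptp(X[:, name_to_col[c]]) > 0]
    kf = KFold(n_splits=min(config.inner_folds, n // 2), shuffle=True,
               random_state=rng_seed)
    folds = list(kf.split(X))
    selected: list[str] = []
    cur_cols = np.empty((n, 0))
    cur_mse = _cv_mse(cur_cols, y, folds)
    # feature budget: the published cap, but never more than one predictor
    # per ~10 observations -- greedy CV selection overfits small groups
    max_feat = min(config.max_features, n - 2, max(1, n // config.obs_per_feature))
    while len(selected) < max_feat:
        remaining = [c for c in usable if c not in selected]
        if not remaining:
            break
        # residual-correlation pre-screen
        beta = _ols(cur_cols, y)
        resid = y - (beta[0] + cur_cols @ beta[1:])
        scores = []
        for c in remaining:
            col = X[:, name_to_col[c]]
            sd = col.std()
            scores.append(abs(np.dot(col - col.mean(), resid)) / sd
                          if sd > 0 else 0.0)
        order = np.argsort(scores)[::-1][:config.selection_screen]
        best_name, best_mse = None, np.inf
        for k in order:
            c = remaining[int(k)]
            cols = np.column_stack([cur_cols, X[:, name_to_col[c]]])
            mse = _cv_mse(cols, y, folds)
            if mse < best_mse:
                best_name, best_mse = c, mse
        if best_name is None or cur_mse - best_mse <= config.selection_tol:
            break
        selected.append(best_name)
        cur_cols = np.column_stack([cur_cols, X[:, name_to_col[best_name]]])
        cur_mse = best_mse
    return selected


def _fit_one(X: np.ndarray, y: np.ndarray, candidates: list[str],
             group: int, target: str, config: RunConfig, rng_seed: int,
             pooled: bool) -> GroupRegressor:
    sel = forward_select(X, y, candidates, config, rng_seed)
    cols = [candidates.index(c) for c in sel]
    beta = _ols(X[:, cols], y)
    return GroupRegressor(group_label=group, target=target,
                          selected_features=sel, coefficients=beta[1:],
                          intercept=float(beta[0]), pooled_fallback=pooled)


def fit_group_regressors(X: np.ndarray, targets_sbp: np.ndarray,
                         targets_dbp: np.ndarray, group_labels: np.ndarray,
                         candidates: list[str],
                         config: RunConfig | None = None, rng_seed: int = 0
                         ) -> dict:
    """Fit the 5 groups x 2 targets = 10 linear models.

    Selection runs independently per group. A group below ``min_group_n``
    inherits the pooled (all-data) model, with a logged warning.
    """
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    groups = np.asarray(group_labels)
    ss = np.random.SeedSequence(rng_seed)
    seeds = iter(int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(12))
    pooled = {
        "sbp": _fit_one(X, np.asarray(targets_sbp, float), candidates, 0,
                        "sbp", config, next(seeds), True),
        "dbp": _fit_one(X, np.asarray(targets_dbp, float), candidates, 0,
                        "dbp", config, next(seeds), True),
    }
    out: dict[tuple[int, str], GroupRegressor] = {}
    for g in (1, 2, 3, 4, 5):
        mask = groups == g
        for target, y in (("sbp", targets_sbp), ("dbp", targets_dbp)):
            seed = next(seeds)
            if mask.sum() < config.min_group_n:
                logger.warning("group %d has %d samples (< %d); using pooled "
                               "%s model", g, int(mask.sum()),
                               config.min_group_n, target)
                base = pooled[target]
                out[(g, target)] = GroupRegressor(
                    group_label=g, target=target,
                    selected_features=list(base.selected_features),
                    coefficients=base.coefficients.copy(),
                    intercept=base.intercept, pooled_fallback=True)
            else:
                out[(g, target)] = _fit_one(
                    X[mask], np.asarray(y, float)[mask], candidates, g,
                    target, config, seed, False)
    return out


@dataclass
class PipelineModel:
    """Everything needed to estimate BP for a new measurement."""

    boundaries: GroupBoundaries
    classifier: GroupClassifier
    regressors: dict                      # (group, target) -> GroupRegressor
    feature_names: list
    config_hash: str = ""
    classifier_feature_names: list = field(default_factory=list)


def estimate_bp(model: PipelineModel, feature_vector: dict) -> BPEstimate:
    """Route one measurement through its predicted group's SBP/DBP models.

    A systolic estimate at or below the diastolic one is resolved by a
    consistency clamp (dbp := sbp - 5 mmHg), flagged on the output.
    """
    missing = [n for n in model.feature_names if n not in feature_vector]
    if missing:
        raise MissingFeatureError(f"missing feature: {missing[0]}")
    clf_names = model.classifier_feature_names or model.feature_names
    x_clf = np.array([feature_vector[n] for n in clf_names], dtype=float)
    group = int(predict_group(model.classifier, x_clf)[0])
    sbp = model.regressors[(group, "sbp")].predict(feature_vector)
    dbp = model.regressors[(group, "dbp")].predict(feature_vector)
    clamped = False
    if sbp <= dbp:
        dbp = sbp - 5.0
        clamped = True
        logger.warning("consistency clamp triggered (sbp_hat <= dbp_hat)")
    return BPEstimate(sbp_hat=float(sbp), dbp_hat=float(dbp),
                      group_used=group, clamped=clamped)
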