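"""Curved-border grouping in the PTT-SBP plane and the bagged SVM classifier.

Training samples are partitioned into five vascular-stiffness groups at
ratio 1:1:3:3:2 by four borders of the family SBP = c / PTT; a point's
band is decided by its coefficient kappa = SBP x PTT. At estimation time
(when no reference SBP exists) the group is predicted by a 35-member
bagged support-vector-machine ensemble with majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import RunConfig
from .errors import ConfigurationError
from .types import GroupBoundaries


def fit_group_boundaries(ptt: np.ndarray, sbp: np.ndarray,
                         mode: str = "quantile") -> GroupBoundaries:
    """Fit the four border coefficients from training (PTT, SBP) pairs.

    ``quantile`` (default) places c4..c1 at the 20/50/80/90th percentiles
    of kappa = SBP x PTT, which guarantees the 1:1:3:3:2 shares (counted
    from the top band down). ``spacing`` reproduces the geometric
    construction instead: the bottom three borders evenly spaced over the
    kappa range and the top border half a spacing above the second.
    """
    ptt = np.asarray(ptt, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    if len(ptt) < 10:
        raise ValueError(f"need >= 10 training points, got {len(ptt)}")
    if np.any(ptt <= 0) or np.any(sbp <= 0):
        raise ValueError("ptt and sbp must be positive")
    kappa = sbp * ptt
    if np.ptp(kappa) == 0:
        raise ValueError("degenerate training set: all kappa identical")
    if mode == "quantile":
        c4, c3, c2, c1 = np.quantile(kappa, [0.2, 0.5, 0.8, 0.9],
                                     method="higher")
    elif mode == "spacing":
        lo, hi = kappa.min(), kappa.max()
        s = (hi - lo) / 4.5
        c4, c3, c2 = lo + s, lo + 2 * s, lo + 3 * s
        c1 = c2 + 0.5 * s
    else:
        raise ConfigurationError(f"unknown border mode: {mode!r}")
    return GroupBoundaries(c1=float(c1), c2=float(c2), c3=float(c3), c4=float(c4))


def assign_group(ptt, sbp, boundaries: GroupBoundaries):
    """Group label 1..5 for (ptt, sbp); accepts scalars or arrays.

    A point exactly on a border takes the higher-BP (lower-numbered) group.
    """
    ptt_a = np.asarray(ptt, dtype=float)
    sbp_a = np.asarray(sbp, dtype=float)
    if np.any(ptt_a <= 0) or np.any(sbp_a <= 0):
        raise ValueError("ptt and sbp must be positive")
    kappa = sbp_a * ptt_a
    labels = 5 - np.searchsorted(boundaries.as_array(), kappa, side="right")
    if np.isscalar(ptt) or labels.ndim == 0:
        return int(labels)
    return labels.astype(int)


@dataclass
class GroupClassifier:
    """Bagged SVM ensemble: 35 members, each on its own bootstrap resample."""

    scaler: StandardScaler
    members: list
    bootstrap_seeds: list
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.bootstrap_seeds):
            raise ValueError("one bootstrap seed per member required")


def train_group_classifier(X: np.ndarray, labels: np.ndarray,
                           config: RunConfig | None = None,
                           rng_seed: int = 0,
                           feature_names: list | None = None,
                           max_retries: int = 100) -> GroupClassifier:
    """Train the bagged ensemble; deterministic for a fixed master seed.

    Standardization is fit on the training set only. Each member is fit on
    an independent bootstrap resample of the same size as the training set;
    a resample that collapses to one class is redrawn (bounded retries).
    """
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two distinct group labels")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svm_c = config.svm_c
    if config.svm_c_grid:
        # optional hyperparameter pass: pick C by 10-fold CV accuracy of a
        # single SVM before bagging
        from sklearn.model_selection import cross_val_score
        counts = np.bincount(y.astype(int))
        k = max(2, min(10, int(counts[counts > 0].min())))
        scores = [np.mean(cross_val_score(
            SVC(C=c, kernel="rbf", gamma=config.svm_gamma), Xs, y, cv=k))
            for c in config.svm_c_grid]
        svm_c = float(config.svm_c_grid[int(np.argmax(scores))])
    ss = np.random.SeedSequence(rng_seed)
    member_seeds = [int(s.generate_state(1)[0] % 2 ** 31)
                    for s in ss.spawn(config.ensemble_size)]
    members = []
    n = len(y)
    for seed in member_seeds:
        rng = np.random.default_rng(seed)
        for attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) >= 2:
                break
        else:
            raise RuntimeError("bootstrap resample kept collapsing to one class")
        svm = SVC(C=svm_c, kernel="rbf", gamma=config.svm_gamma)
        svm.fit(Xs[idx], y[idx])
        members.append(svm)
    return GroupClassifier(scaler=scaler, members=members,
                           bootstrap_seeds=member_seeds,
                           feature_names=list(feature_names or []))


def member_votes(classifier: GroupClassifier, X: np.ndarray) -> np.ndarray:
    """(n_members, n_samples) matrix of individual member predictions."""
    Xs = classifier.scaler.transform(np.asarray(X, dtype=float))
    return np.vstack([m.predict(Xs) for m in classifier.members])


def predict_group(classifier: GroupClassifier, X: np.ndarray) -> np.ndarray:
    """Majority vote over the 35 members; ties go to the lowest group number
    (the higher-BP call). Accepts a single vector or a matrix."""
    if not classifier.members:
        raise ValueError("classifier has no trained members")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    votes = member_votes(classifier, X)
    out = np.empty(votes.shape[1], dtype=int)
    for j in range(votes.shape[1]):
        counts = np.bincount(votes[:, j].astype(int), minlength=6)
        out[j] = int(np.argmax(counts[1:]) + 1)   # argmax takes lowest on ties
    return out
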