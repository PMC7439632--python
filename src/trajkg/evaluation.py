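"""Repeated, fold-matched cross-validation of random-forest classifiers.

The protocol: 10 repeats of stratified 10-fold cross-validation; the AUC of
the out-of-fold class probabilities is recorded per (repeat, fold).  The
*same* fold assignment is reused for every feature variant of a paired run,
so variants can be compared fold-by-fold with a two-sided paired t-test.
Class-imbalance control is by seeded undersampling, and operating points are
reported at the probability cutoff maximizing the Youden index
(sensitivity + specificity - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

#: Random-forest defaults (hyperparameters are deliberately plain: a
#: moderately large forest with sqrt-features splits and probability output).
DEFAULT_RF_PARAMS: dict = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "n_jobs": 1,
}


def _as_array(matrix):
    """Accept a FeatureMatrix, sparse matrix or ndarray."""
    inner = getattr(matrix, "matrix", matrix)
    return inner


def _seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-component child seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def make_fold_map(
    labels: np.ndarray, repeats: int, folds: int, seed: int
) -> np.ndarray:
    """Stratified fold assignments, shape (repeats, n): fold index per sample.

    Each repeat reshuffles with its own seed derived from *seed*.  Requires
    at least *folds* members of each class so that every test fold contains
    both classes.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: minority class has only "
            f"{counts.min()} members"
        )
    fold_map = np.empty((repeats, len(labels)), dtype=np.int64)
    for r, s in enumerate(_seeds(seed, repeats)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(s))
        for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                    labels)):
            fold_map[r, test_idx] = k
    return fold_map


@dataclass
class CVResult:
    """Per-(repeat, fold) test AUCs of one feature variant.

    ``oof_scores[r, i]`` is the out-of-fold class-probability score of sample
    *i* in repeat *r*; ``fold_map`` records the assignment that produced it.
    """

    variant: str
    aucs: np.ndarray            # (repeats, folds)
    fold_map: np.ndarray        # (repeats, n)
    oof_scores: np.ndarray      # (repeats, n)
    labels: np.ndarray          # (n,)
    seed: int

    @property
    def repeats(self) -> int:
        return self.aucs.shape[0]

    @property
    def folds(self) -> int:
        return self.aucs.shape[1]

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        """Standard deviation over all repeat x fold AUCs (ddof=1)."""
        return float(self.aucs.std(ddof=1))

    @property
    def repeat_means(self) -> np.ndarray:
        return self.aucs.mean(axis=1)


def run_cv(
    matrix,
    labels: Sequence[int],
    *,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    model_params: Mapping | None = None,
    fold_map: np.ndarray | None = None,
    variant_name: str = "",
) -> CVResult:
    """Repeated stratified CV of a random forest; AUC per test fold.

    Passing a precomputed ``fold_map`` reuses fold assignments across
    variants, which is required for paired comparisons.
    """
    X = _as_array(matrix)
    y = np.asarray(labels)
    if X.shape[0] != len(y):
        raise ValueError("matrix rows do not align with labels")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if fold_map is None:
        fold_map = make_fold_map(y, repeats, folds, seed)
    else:
        fold_map = np.asarray(fold_map)
        if fold_map.shape != (repeats, len(y)):
            raise ValueError("fold_map shape does not match (repeats, n)")

    params = dict(DEFAULT_RF_PARAMS)
    if model_params:
        params.update(model_params)
    rf_seeds = _seeds(seed + 1, repeats * folds).reshape(repeats, folds)

    aucs = np.empty((repeats, folds))
    oof = np.empty((repeats, len(y)))
    for r in range(repeats):
        for k in range(folds):
            test = fold_map[r] == k
            train = ~test
            y_test = y[test]
            if len(np.unique(y_test)) < 2 or len(np.unique(y[train])) < 2:
                raise ValueError(
                    f"fold {k} of repeat {r} lacks one class; use stratified "
                    f"folds with enough members per class"
                )
            clf = RandomForestClassifier(
                random_state=int(rf_seeds[r, k]), **params
            )
            clf.fit(X[train], y[train])
            pos = list(clf.classes_).index(1)
            scores = clf.predict_proba(X[test])[:, pos]
            oof[r, test] = scores
            aucs[r, k] = roc_auc_score(y_test, scores)
    return CVResult(variant_name, aucs, fold_map, oof, y, seed)


@dataclass
class PairedComparison:
    """Two-sided paired t-test between the matched fold AUCs of two variants."""

    variant_a: str
    variant_b: str
    differences: np.ndarray
    t_statistic: float
    p_value: float
    df: int

    @property
    def mean_difference(self) -> float:
        return float(self.differences.mean())


def paired_fold_ttest(
    a: CVResult, b: CVResult, *, granularity: str = "fold"
) -> PairedComparison:
    """Paired t-test over matched per-fold AUCs of two CV results.

    Requires identical fold maps (an unpaired comparison is refused).  With
    ``granularity="repeat"`` the pairing is over per-repeat mean AUCs
    instead of all repeat x fold cells.  Identical AUCs everywhere yield the
    "no difference" convention t=0, p=1.
    """
    if a.fold_map.shape != b.fold_map.shape or not np.array_equal(
        a.fold_map, b.fold_map
    ):
        raise ValueError(
            "fold maps differ between the two CV results; paired comparison "
            "requires identical fold assignments"
        )
    if granularity == "fold":
        xa, xb = a.aucs.ravel(), b.aucs.ravel()
    elif granularity == "repeat":
        xa, xb = a.repeat_means, b.repeat_means
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    diffs = xa - xb
    if np.allclose(diffs, 0.0):
        return PairedComparison(a.variant, b.variant, diffs, 0.0, 1.0,
                                len(diffs) - 1)
    t, p = scipy.stats.ttest_rel(xa, xb)
    return PairedComparison(a.variant, b.variant, diffs, float(t), float(p),
                            len(diffs) - 1)


def undersample(
    labels: Sequence[int], n_pos: int, n_neg: int, seed: int
) -> np.ndarray:
    """Indices of a uniform, seeded subsample with exact class counts.

    Sampling is without replacement; the returned indices are sorted.
    """
    y = np.asarray(labels)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if n_pos > len(pos) or n_neg > len(neg):
        raise ValueError(
            f"requested {n_pos} positives / {n_neg} negatives but only "
            f"{len(pos)} / {len(neg)} available"
        )
    rng = np.random.default_rng(seed)
    take = np.concatenate([
        rng.choice(pos, size=n_pos, replace=False),
        rng.choice(neg, size=n_neg, replace=False),
    ])
    return np.sort(take)


@dataclass
class YoudenResult:
    """Operating point maximizing the Youden index J = sens + spec - 1."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    thresholds: np.ndarray = field(repr=False, default=None)


def roc_youden(scores: Sequence[float], labels: Sequence[int]) -> YoudenResult:
    """ROC curve over all observed thresholds and its Youden-optimal point.

    Ties at the maximal J are broken by higher sensitivity, then by lower
    threshold.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[tpr[best] >= tpr[best].max() - 1e-12]
    idx = best[np.argmin(thr[best])]
    return YoudenResult(
        threshold=float(thr[idx]),
        sensitivity=float(tpr[idx]),
        specificity=float(1.0 - fpr[idx]),
        youden_j=float(j[idx]),
        fpr=fpr, tpr=tpr, thresholds=thr,
    )
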