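"""Biomarker evaluation: ROC curves, metabolite ratios, Monte-Carlo
multivariate ROC with random-forest feature ranking, and SVM validation.

The multivariate ROC follows the repeated-subsampling scheme common in
metabolomics biomarker modules: many stratified 2/3-1/3 splits, features
ranked by random-forest importance on each training portion, a classifier
refit on the top-ranked features, and held-out class probabilities pooled
(averaged per sample) into a single ROC/AUC estimate, alongside the
frequency with which each feature enters the top set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DataError, LeakageError


@dataclass
class RocResult:
    """ROC points, trapezoidal AUC, Youden cutoff and per-sample probabilities."""

    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing
    thresholds: np.ndarray
    auc: float
    cutoff: float  # score value at the maximum Youden index
    polarity: int  # +1 if higher score favors the positive class, else -1
    positive_class: str
    per_sample_prob: pd.Series | None = None

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def summary(self) -> dict:
        return {
            "auc": float(self.auc),
            "cutoff": float(self.cutoff),
            "polarity": self.polarity,
            "positive_class": self.positive_class,
            "n_points": len(self.fpr),
        }


def _binary(labels) -> tuple[np.ndarray, str]:
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise DataError(f"ROC needs exactly two classes, got {classes}")
    positive = str(classes[1])
    return (labels == classes[1]).astype(int), positive


def roc_curve(scores, labels, orient: bool = True) -> RocResult:
    """ROC by threshold sweep over the score values.

    AUC is the trapezoidal area (equal to the concordant-pair fraction with
    ties counted 1/2). With `orient` the score polarity is chosen so
    AUC >= 0.5 and recorded; the cutoff is the score (on the original
    scale) maximizing sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    y, positive = _binary(labels)
    polarity = 1
    auc = float(skmetrics.roc_auc_score(y, scores))
    if orient and auc < 0.5:
        polarity, scores, auc = -1, -scores, 1.0 - auc
    fpr, tpr, thr = skmetrics.roc_curve(y, scores)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff = float(polarity * thr[best])
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=polarity * thr, auc=auc,
        cutoff=cutoff, polarity=polarity, positive_class=positive,
    )


def ratio_feature(quant: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """Per-sample metabolite ratio; refuses nonpositive denominators."""
    for name in (numerator, denominator):
        if name not in quant.columns:
            raise DataError(f"metabolite {name!r} not in quantification table")
    den = quant[denominator]
    bad = den.index[den <= 0].tolist()
    if bad:
        raise DataError(f"nonpositive {denominator!r} for samples: {bad}")
    out = quant[numerator] / den
    out.name = f"{numerator}/{denominator}"
    return out


@dataclass
class FeatureRanking:
    """Selection frequency of each feature in the Monte-Carlo top sets."""

    frequency: pd.Series  # sorted descending, ties broken alphabetically

    @property
    def order(self) -> list[str]:
        return self.frequency.index.tolist()


def multivariate_roc(
    quant: pd.DataFrame,
    labels,
    n_features: int = 5,
    n_splits: int = 100,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[RocResult, FeatureRanking]:
    """Monte-Carlo cross-validated ROC with random-forest feature ranking.

    Repeated stratified 2/3 train, 1/3 test splits; per split, features are
    ranked by random-forest impurity importance on the training portion,
    the top `n_features` kept, a fresh forest fit on them, and held-out
    probabilities collected. The pooled per-sample average probabilities
    give the ROC/AUC; the ranking reports how often each feature made a
    split's top set.
    """
    if n_splits < 10:
        raise ConfigError("n_splits must be >= 10 for stable estimates")
    if n_features < 1 or n_features > quant.shape[1]:
        raise ConfigError(f"n_features must be in [1, {quant.shape[1]}]")
    y, positive = _binary(labels)
    X = quant.to_numpy(dtype=float)
    features = np.asarray(quant.columns)

    sss = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=1 / 3, random_state=int(seed) % (2**32)
    )
    prob_sum = np.zeros(len(y))
    prob_count = np.zeros(len(y), dtype=int)
    selected = np.zeros(len(features), dtype=int)
    rng = np.random.default_rng(seed)
    for train, test in sss.split(X, y):
        rs = int(rng.integers(2**31))
        ranker = RandomForestClassifier(n_estimators=n_trees, random_state=rs)
        ranker.fit(X[train], y[train])
        # stable top set: importance descending, ties alphabetical
        order = np.lexsort((features, -ranker.feature_importances_))
        top = np.sort(order[:n_features])
        selected[top] += 1
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=rs + 1)
        clf.fit(X[train][:, top], y[train])
        prob = clf.predict_proba(X[test][:, top])[:, list(clf.classes_).index(1)]
        prob_sum[test] += prob
        prob_count[test] += 1

    tested = prob_count > 0
    avg_prob = prob_sum[tested] / prob_count[tested]
    roc = roc_curve(avg_prob, np.asarray(labels)[tested], orient=False)
    roc.per_sample_prob = pd.Series(avg_prob, index=quant.index[tested], name="prob")

    freq = pd.Series(selected / n_splits, index=features, name="selected_frequency")
    freq = freq.iloc[np.lexsort((freq.index, -freq.to_numpy()))]
    return roc, FeatureRanking(frequency=freq)


def svm_validate(
    train_features,
    train_labels,
    test_features,
    test_labels,
    train_ids=None,
    test_ids=None,
) -> dict:
    """Linear-kernel SVM trained on one cohort, evaluated on a disjoint one.

    Returns accuracy plus per-class sensitivity (positive-class recall) and
    specificity. Overlapping sample ids raise :class:`LeakageError`.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(map(str, train_ids)) & set(map(str, test_ids))
        if overlap:
            raise LeakageError(f"train/test share sample ids: {sorted(overlap)}")
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    if Xtr.ndim == 1:
        Xtr, Xte = Xtr[:, None], Xte[:, None]
    ytr, positive = _binary(train_labels)
    yte = (np.asarray(test_labels) == positive).astype(int)

    clf = make_pipeline(StandardScaler(), SVC(kernel="linear"))
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    acc = float((pred == yte).mean())
    sens = float((pred[yte == 1] == 1).mean()) if (yte == 1).any() else float("nan")
    spec = float((pred[yte == 0] == 0).mean()) if (yte == 0).any() else float("nan")
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "positive_class": positive,
    }
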