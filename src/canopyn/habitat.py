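"""Supervised classification of favorable folivore feeding habitat.

Crown pixels are labeled favorable (1) when their tree's canopy nitrogen is
at or above 1% dry matter — the classical browse-quality threshold for
arboreal folivores — and unfavorable (0) below it.  A balanced subsample
(default 25,000 pixels per class) trains a binomial random forest on the
19 spectral features; skill is reported on a held-out split as accuracy,
sensitivity, specificity, the true skill statistic TSS = TPR + TNR - 1,
Cohen's kappa, rank-based AUC, and the operating threshold that maximizes
TPR + TNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = ["label_pixels", "balance_subsample", "HabitatForestClassifier",
           "confusion_metrics", "auc", "operating_threshold",
           "ClassifierEval", "evaluate_classifier"]

N_THRESHOLD_PCT_DM = 1.0    # favorable feeding habitat: N >= 1% dry matter


def label_pixels(pixels: pd.DataFrame, trees: pd.DataFrame,
                 threshold_pct_dm: float = N_THRESHOLD_PCT_DM) -> pd.DataFrame:
    """Attach the binary habitat label to every pixel row.

    label = 1 iff the pixel's source tree has N >= threshold (boundary
    inclusive: a tree at exactly 1.00 % DM is favorable).  Raises if any
    pixel's tree lacks an N value.
    """
    n_by_tree = trees.set_index("tree_id")["n_pct_dm"]
    tree_n = n_by_tree.reindex(pixels["tree_id"]).to_numpy(float)
    bad = pixels.loc[np.isnan(tree_n), "tree_id"].unique()
    if len(bad):
        raise ValueError(f"trees with missing N values: {sorted(bad)}")
    out = pixels.copy()
    out["label"] = (tree_n >= threshold_pct_dm).astype(int)
    return out


def balance_subsample(labeled: pd.DataFrame, n_per_class: int = 25_000,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Equal-count class subsample, drawn without replacement and shuffled.

    When one class has fewer than ``n_per_class`` rows, all of it is taken
    and the other class is matched to that count (with a warning).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = labeled["label"].value_counts()
    if set(counts.index) != {0, 1}:
        raise ValueError("both classes must be present to balance")
    take = min(n_per_class, counts.min())
    if take < n_per_class:
        warnings.warn(
            f"minority class has {counts.min()} rows < requested "
            f"{n_per_class}; taking {take} per class", stacklevel=2)
    parts = []
    for cls in (0, 1):
        members = np.flatnonzero(labeled["label"].to_numpy() == cls)
        parts.append(labeled.iloc[rng.choice(members, size=take, replace=False)])
    out = pd.concat(parts)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


class HabitatForestClassifier(BaseEstimator, ClassifierMixin):
    """Binomial random forest over spectral features.

    A thin sklearn-style wrapper pinning the features used (typically the
    predictors selected by the nitrogen model) and exposing per-pixel
    probability of the favorable class.
    """

    def __init__(self, features: list[str] | None = None,
                 n_estimators: int = 500, mtry: int | None = None,
                 random_state: int | None = None):
        self.features = features
        self.n_estimators = n_estimators
        self.mtry = mtry
        self.random_state = random_state

    #: bookkeeping columns never used as predictors
    NON_FEATURE = ("label", "tree_id", "row", "col")

    def _columns(self, X: pd.DataFrame) -> list[str]:
        if self.features is not None:
            cols = list(self.features)
        else:
            cols = [c for c in X.columns if c not in self.NON_FEATURE]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        return cols

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        cols = self._columns(X)
        self.feature_names_ = cols
        p = len(cols)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.mtry or max(1, int(np.sqrt(p))),
            random_state=self.random_state)
        self.forest_.fit(X[cols].to_numpy(float), y)
        self.classes_ = self.forest_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = pd.DataFrame(X)
        return self.forest_.predict_proba(X[self.feature_names_].to_numpy(float))

    def predict_score(self, X) -> np.ndarray:
        """Probability of the favorable class (label 1)."""
        proba = self.predict_proba(X)
        col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, col]

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Skill metrics from the four confusion cells.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), TSS = sensitivity + specificity - 1, plus
    Cohen's kappa.  An empty class makes the affected rate NaN.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion matrix is empty")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    p_obs = (tp + tn) / total
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((tn + fn) / total) * ((tn + fp) / total)
    p_exp = p_yes + p_no
    kappa = (p_obs - p_exp) / (1 - p_exp) if p_exp != 1 else float("nan")
    return {"accuracy": p_obs, "sensitivity": sens, "specificity": spec,
            "tss": sens + spec - 1, "kappa": kappa, "n": int(total)}


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half.

    NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def operating_threshold(scores, labels) -> tuple[float, float]:
    """Score cutoff maximizing TPR + TNR (classification >= threshold).

    Candidate thresholds are the unique score values; ties in TPR + TNR
    break toward the lowest threshold.  Returns (threshold, tpr + tnr).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to choose a threshold")
    candidates = np.unique(scores)
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n_pos
        tnr = (~pred & (labels == 0)).sum() / n_neg
        j = tpr + tnr
        if j > best_j:        # strict: ties keep the lowest threshold
            best_t, best_j = float(t), float(j)
    return best_t, best_j


@dataclass
class ClassifierEval:
    """Held-out evaluation at the chosen operating threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    auc: float
    threshold: float
    n_holdout: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_classifier(balanced: pd.DataFrame,
                        features: list[str] | None = None,
                        test_fraction: float = 0.3,
                        n_estimators: int = 500,
                        seed: int | None = None
                        ) -> tuple[HabitatForestClassifier, ClassifierEval]:
    """Train on 70% of the balanced pixel set, evaluate on the held-out 30%.

    The operating threshold (max TPR + TNR) is chosen on the held-out scores
    and the confusion matrix is reported at that threshold.
    """
    y = balanced["label"].to_numpy(int)
    idx_train, idx_test = train_test_split(
        np.arange(len(balanced)), test_size=test_fraction,
        random_state=seed, stratify=y)
    clf = HabitatForestClassifier(features=features, n_estimators=n_estimators,
                                  random_state=seed)
    clf.fit(balanced.iloc[idx_train], y[idx_train])
    scores = clf.predict_score(balanced.iloc[idx_test])
    y_test = y[idx_test]
    thr, _ = operating_threshold(scores, y_test)
    pred = scores >= thr
    tp = int((pred & (y_test == 1)).sum())
    fp = int((pred & (y_test == 0)).sum())
    tn = int((~pred & (y_test == 0)).sum())
    fn = int((~pred & (y_test == 1)).sum())
    m = confusion_metrics(tp, fp, tn, fn)
    ev = ClassifierEval(tp=tp, fp=fp, tn=tn, fn=fn,
                        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
                        specificity=m["specificity"], tss=m["tss"],
                        kappa=m["kappa"], auc=auc(scores, y_test),
                        threshold=thr, n_holdout=len(y_test))
    return clf, ev
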