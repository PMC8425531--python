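"""Two-step gradient-boosted classification of aligned mutation profiles.

Step one extracts features: depth-2 boosted trees are trained on each of
4 stratified folds and feature importances (total split gain, averaged
over folds) rank the aligned (m, d) columns; the top 30 are kept.  Step
two trains depth-1 boosted trees on the selected columns, again with
4-fold cross-validation, reporting per-fold AUC, accuracy, sensitivity
and specificity.  A classifier is built for every unordered pair of
classes (K classes give K(K-1)/2 reports) and, separately, a soft-
probability multiclass model.

Feature selection is deliberately not nested inside the evaluation folds:
both steps run on the full (pair) cohort with fold-averaged importances.
Cross-validated metrics therefore carry a selection-leakage optimism;
null-calibration checks must re-run the full two-step pipeline on
permuted labels so the reference interval carries the same bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import LabelEncoder
from xgboost import XGBClassifier

from .align import AlignedMatrix


@dataclass(frozen=True)
class ClassifierConfig:
    n_folds: int = 4
    extraction_max_depth: int = 2
    final_max_depth: int = 1
    n_top_features: int = 30
    n_estimators: int = 100
    learning_rate: float = 0.3
    rng_seed: int = 0
    balance_classes: bool = False

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.extraction_max_depth < 1 or self.final_max_depth < 1:
            raise ValueError("tree depths must be >= 1")
        if self.n_top_features < 1:
            raise ValueError("n_top_features must be >= 1")


def _xgb(max_depth: int, config: ClassifierConfig, n_classes: int) -> XGBClassifier:
    kwargs = dict(
        max_depth=max_depth,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        random_state=config.rng_seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    if n_classes > 2:
        kwargs.update(objective="multi:softprob", num_class=n_classes)
    else:
        kwargs.update(objective="binary:logistic", eval_metric="logloss")
    return XGBClassifier(**kwargs)


def _check_stratifiable(y: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs at least n_folds={n_folds} samples for "
            f"stratified cross-validation (smallest class has {counts.min()})"
        )


class BoostedFeatureSelector(BaseEstimator):
    """Rank features by fold-averaged total-gain importance of depth-2
    boosted trees; keep the top ``n_top_features`` (ties by column order)."""

    def __init__(
        self,
        n_folds: int = 4,
        max_depth: int = 2,
        n_top_features: int = 30,
        n_estimators: int = 100,
        learning_rate: float = 0.3,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.max_depth = max_depth
        self.n_top_features = n_top_features
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        enc = LabelEncoder().fit(y)
        y_enc = enc.transform(y)
        _check_stratifiable(y_enc, self.n_folds)
        config = ClassifierConfig(
            n_folds=self.n_folds,
            extraction_max_depth=self.max_depth,
            n_top_features=self.n_top_features,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            rng_seed=self.random_state,
        )
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        gains = np.zeros(X.shape[1])
        for train_idx, _ in skf.split(X, y_enc):
            model = _xgb(self.max_depth, config, len(enc.classes_))
            model.fit(X[train_idx], y_enc[train_idx])
            score = model.get_booster().get_score(importance_type="total_gain")
            for name, gain in score.items():
                gains[int(name[1:])] += gain
        gains /= self.n_folds
        self.importances_ = gains
        # stable sort keeps column order on ties
        self.ranking_ = np.argsort(-gains, kind="stable")
        self.selected_features_ = np.sort(self.ranking_[: self.n_top_features])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.selected_features_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_features_] = True
        return mask


class TwoStepBoostedClassifier(BaseEstimator, ClassifierMixin):
    """Depth-2 boosted feature extraction, then a depth-1 boosted
    classifier on the top features, evaluated by stratified CV.

    Fitted attributes: ``selector_`` (the step-one selector),
    ``cv_results_`` (per-fold metric dict), ``oof_proba_`` (out-of-fold
    class probabilities, samples × classes), ``folds_`` (the CV index
    pairs), ``final_model_`` (depth-1 model refit on all samples, used by
    predict/predict_proba).
    """

    def __init__(
        self,
        n_folds: int = 4,
        extraction_max_depth: int = 2,
        final_max_depth: int = 1,
        n_top_features: int = 30,
        n_estimators: int = 100,
        learning_rate: float = 0.3,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.extraction_max_depth = extraction_max_depth
        self.final_max_depth = final_max_depth
        self.n_top_features = n_top_features
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            n_folds=self.n_folds,
            extraction_max_depth=self.extraction_max_depth,
            final_max_depth=self.final_max_depth,
            n_top_features=self.n_top_features,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            rng_seed=self.random_state,
        )

    def fit(self, X, y):
        config = self._config()
        config.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        y_enc = self._encoder.transform(y)
        _check_stratifiable(y_enc, self.n_folds)
        n_classes = len(self.classes_)

        self.selector_ = BoostedFeatureSelector(
            n_folds=self.n_folds,
            max_depth=self.extraction_max_depth,
            n_top_features=self.n_top_features,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
        ).fit(X, y)
        Xs = self.selector_.transform(X)

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        self.folds_ = list(skf.split(Xs, y_enc))
        self.oof_proba_ = np.zeros((len(y), n_classes))
        fold_metrics: list[dict[str, float]] = []
        self.roc_points_ = []
        for train_idx, val_idx in self.folds_:
            model = _xgb(self.final_max_depth, config, n_classes)
            model.fit(Xs[train_idx], y_enc[train_idx])
            proba = model.predict_proba(Xs[val_idx])
            self.oof_proba_[val_idx] = proba
            fold_metrics.append(
                _fold_metrics(y_enc[val_idx], proba, n_classes)
            )
            if n_classes == 2:
                fpr, tpr, thr = roc_curve(y_enc[val_idx], proba[:, 1])
                self.roc_points_.append(
                    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
                )
        self.cv_results_ = {
            key: np.array([fm[key] for fm in fold_metrics])
            for key in fold_metrics[0]
        }
        self.final_model_ = _xgb(self.final_max_depth, config, n_classes)
        self.final_model_.fit(Xs, y_enc)
        return self

    def predict_proba(self, X):
        Xs = self.selector_.transform(np.asarray(X, dtype=float))
        return self.final_model_.predict_proba(Xs)

    def predict(self, X):
        return self._encoder.inverse_transform(
            np.argmax(self.predict_proba(X), axis=1)
        )


def _fold_metrics(y_true: np.ndarray, proba: np.ndarray, n_classes: int) -> dict:
    pred = np.argmax(proba, axis=1)
    out = {"accuracy": float(np.mean(pred == y_true))}
    if n_classes == 2:
        # class 1 (encoded) is the positive class; threshold 0.5
        pos = (proba[:, 1] >= 0.5).astype(int)
        tp = int(np.sum((pos == 1) & (y_true == 1)))
        tn = int(np.sum((pos == 0) & (y_true == 0)))
        fp = int(np.sum((pos == 1) & (y_true == 0)))
        fn = int(np.sum((pos == 0) & (y_true == 1)))
        out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
        out["accuracy"] = (tp + tn) / len(y_true)
        out["auc"] = float(roc_auc_score(y_true, proba[:, 1]))
    return out


@dataclass
class PairwiseReport:
    class_a: str
    class_b: str
    auc: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    selected_features: list[str]
    importances: np.ndarray
    roc_points: list[pd.DataFrame] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc, ddof=1))

    def summary(self) -> dict:
        out = {"class_a": self.class_a, "class_b": self.class_b}
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            vals = getattr(self, name)
            out[f"mean_{name}"] = float(np.mean(vals))
            out[f"sd_{name}"] = float(np.std(vals, ddof=1))
        return out


@dataclass
class MulticlassReport:
    classes: list[str]
    proba_profile: pd.DataFrame     # out-of-fold, samples × classes
    fold_accuracy: np.ndarray
    confusion: pd.DataFrame


def _resolve(matrix: AlignedMatrix, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = matrix.values.to_numpy(dtype=float)
    if labels is None:
        if matrix.labels is None:
            raise ValueError("labels are required (none stored on the matrix)")
        y = matrix.labels.to_numpy()
    else:
        y = pd.Series(labels).reindex(matrix.values.index).to_numpy()
    if pd.isna(y).any():
        raise ValueError("every sample needs a class label")
    return X, y, list(matrix.values.columns)


def select_features(
    matrix: AlignedMatrix, labels=None, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Rank all aligned columns by fold-averaged total gain (step one)."""
    config = config or ClassifierConfig()
    config.validate()
    X, y, names = _resolve(matrix, labels)
    sel = BoostedFeatureSelector(
        n_folds=config.n_folds,
        max_depth=config.extraction_max_depth,
        n_top_features=config.n_top_features,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        random_state=config.rng_seed,
    ).fit(X, y)
    ranked = sel.ranking_
    return pd.DataFrame(
        {
            "feature": [names[i] for i in ranked],
            "column": ranked,
            "importance": sel.importances_[ranked],
            "selected": [i in set(sel.selected_features_) for i in ranked],
        }
    )


def _fit_two_step(X, y, config: ClassifierConfig) -> TwoStepBoostedClassifier:
    return TwoStepBoostedClassifier(
        n_folds=config.n_folds,
        extraction_max_depth=config.extraction_max_depth,
        final_max_depth=config.final_max_depth,
        n_top_features=config.n_top_features,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        random_state=config.rng_seed,
    ).fit(X, y)


def train_pairwise(
    matrix: AlignedMatrix, labels=None, config: ClassifierConfig | None = None
) -> list[PairwiseReport]:
    """One two-step classifier per unordered class pair.

    Features are re-selected on each pair's samples only.  ``class_a``
    (the alphabetically later label is encoded as the positive class by
    the label encoder; class_a is reported as the positive one here).
    """
    config = config or ClassifierConfig()
    config.validate()
    X, y, names = _resolve(matrix, labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    reports = []
    for a, b in combinations(classes, 2):
        mask = np.isin(y, [a, b])
        clf = _fit_two_step(X[mask], y[mask], config)
        # encoded positive class is clf.classes_[1]
        pos = str(clf.classes_[1])
        neg = str(clf.classes_[0])
        reports.append(
            PairwiseReport(
                class_a=pos,
                class_b=neg,
                auc=clf.cv_results_["auc"],
                accuracy=clf.cv_results_["accuracy"],
                sensitivity=clf.cv_results_["sensitivity"],
                specificity=clf.cv_results_["specificity"],
                selected_features=[names[i] for i in clf.selector_.selected_features_],
                importances=clf.selector_.importances_[
                    clf.selector_.selected_features_
                ],
                roc_points=clf.roc_points_,
            )
        )
    return reports


def train_multiclass(
    matrix: AlignedMatrix, labels=None, config: ClassifierConfig | None = None
) -> MulticlassReport:
    """Soft-probability multiclass model with the same two-step scheme."""
    config = config or ClassifierConfig()
    config.validate()
    X, y, _ = _resolve(matrix, labels)
    classes = sorted(set(y))
    if len(classes) < 3:
        raise ValueError("multiclass training needs at least three classes")
    clf = _fit_two_step(X, y, config)
    # boosters emit float32 softmax rows; renormalize so rows sum to 1 exactly
    oof = clf.oof_proba_ / clf.oof_proba_.sum(axis=1, keepdims=True)
    proba = pd.DataFrame(oof, index=matrix.values.index, columns=list(clf.classes_))
    pred = clf.classes_[np.argmax(clf.oof_proba_, axis=1)]
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=list(clf.classes_)),
        index=list(clf.classes_),
        columns=list(clf.classes_),
    )
    return MulticlassReport(
        classes=list(clf.classes_),
        proba_profile=proba,
        fold_accuracy=clf.cv_results_["accuracy"],
        confusion=conf,
    )


def report_metrics(reports: list[PairwiseReport]) -> dict:
    """Summary tables for a batch of pairwise reports.

    Returns a dict with ``summary`` (mean ± sd per pair), a symmetric
    ``seriation`` matrix per metric (empty diagonal) and concatenated ROC
    points.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    for rep in reports:
        if not rep.roc_points:
            raise ValueError(
                f"report {rep.class_a} vs {rep.class_b} carries no ROC data"
            )
    summary = pd.DataFrame([rep.summary() for rep in reports])
    classes = sorted({c for rep in reports for c in (rep.class_a, rep.class_b)})
    seriation = {}
    for metric in ("auc", "accuracy", "sensitivity", "specificity"):
        grid = pd.DataFrame(np.nan, index=classes, columns=classes)
        for rep in reports:
            val = float(np.mean(getattr(rep, metric)))
            grid.loc[rep.class_a, rep.class_b] = val
            grid.loc[rep.class_b, rep.class_a] = val
        seriation[metric] = grid
    roc_frames = []
    for rep in reports:
        for fold, pts in enumerate(rep.roc_points):
            df = pts.copy()
            df.insert(0, "fold", fold)
            df.insert(0, "class_b", rep.class_b)
            df.insert(0, "class_a", rep.class_a)
            roc_frames.append(df)
    return {
        "summary": summary,
        "seriation": seriation,
        "roc_points": pd.concat(roc_frames, ignore_index=True),
    }
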