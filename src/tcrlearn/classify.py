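"""Binary classification of repertoire samples from selected features.

Four transparent classifiers are offered — Gaussian Naive Bayes (GNB),
Linear Discriminant Analysis (LDA), Logistic Regression (LR) and Decision
Tree (DT) — evaluated with five metrics (accuracy, precision, recall, F1,
AUC-ROC) plus the confusion matrix.  Internal validation is repeated
stratified k-fold (default threefold, 100 repeats, reshuffled each repeat);
external validation applies a frozen model, including its frozen
normalization, to an independent cohort with no refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .errors import (ConfigurationError, ContractError, DegenerateSampleError,
                     NonTransferableFeatureError)
from .io import FeatureTable
from .preprocess import FeatureScaler
from .selection import encode_labels

ALGORITHMS = ("GNB", "LDA", "LR", "DT")

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")

DEFAULT_K_FOLDS = 3
DEFAULT_REPEATS = 100


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "GNB":
        return GaussianNB()
    if algorithm == "LDA":
        return LinearDiscriminantAnalysis()
    if algorithm == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed)
    raise ConfigurationError(
        f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
    )


def metrics(y_true, y_pred, y_score=None, positive_class=1) -> dict:
    """The five scoring metrics and the confusion matrix for one prediction.

    ``y_score`` is the positive-class probability; AUC uses the mid-rank
    convention for ties (0.5 for a constant score).  Precision is 0, with a
    warning, when nothing is predicted positive.
    """
    yt = np.asarray([1 if y == positive_class else 0 for y in y_true])
    yp = np.asarray([1 if y == positive_class else 0 for y in y_pred])
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    out = {"accuracy": (tp + tn) / len(yt)}
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        out["precision"] = 0.0
    else:
        out["precision"] = tp / (tp + fp)
    out["recall"] = tp / (tp + fn) if (tp + fn) else 0.0
    p, r = out["precision"], out["recall"]
    out["f1"] = 2 * p * r / (p + r) if (p + r) else 0.0
    if y_score is None:
        out["auc"] = np.nan
    elif len(set(yt)) < 2:
        out["auc"] = np.nan
    else:
        out["auc"] = float(roc_auc_score(yt, np.asarray(y_score, dtype=float)))
    # rows = true (neg, pos), cols = predicted (neg, pos)
    out["confusion_matrix"] = np.array([[tn, fp], [fn, tp]], dtype=int)
    return out


@dataclass
class EvaluationReport:
    """Mean and dispersion of each metric over fold evaluations, the summed
    confusion matrix, and the fold scheme used."""

    means: dict
    stds: dict
    confusion_matrix: np.ndarray
    scheme: dict = field(default_factory=dict)
    class_names: tuple = ("negative", "positive")

    def to_frame(self) -> pd.DataFrame:
        rows = {m: {"mean": self.means[m], "std": self.stds.get(m, 0.0)}
                for m in METRIC_NAMES if m in self.means}
        neg, pos = self.class_names
        cm = self.confusion_matrix
        rows[f"cm_true_{neg}_pred_{neg}"] = {"mean": cm[0, 0], "std": 0.0}
        rows[f"cm_true_{neg}_pred_{pos}"] = {"mean": cm[0, 1], "std": 0.0}
        rows[f"cm_true_{pos}_pred_{neg}"] = {"mean": cm[1, 0], "std": 0.0}
        rows[f"cm_true_{pos}_pred_{pos}"] = {"mean": cm[1, 1], "std": 0.0}
        df = pd.DataFrame(rows).T
        df.index.name = "metric"
        return df


class RepertoireClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier over a feature table, storing its full prediction
    contract: ordered feature names, frozen normalization, positive class
    and seed.

    Parameters
    ----------
    algorithm : {"GNB", "LDA", "LR", "DT"}
    normalization : {"standard", "minmax", "robust", "none"}
        Fitted on the training features and frozen into the model.
    positive_class : label or None
        Defaults to the second label in sorted order.
    random_state : int
    """

    def __init__(self, algorithm: str = "DT", normalization: str = "none",
                 positive_class=None, random_state: int = 0):
        self.algorithm = algorithm
        self.normalization = normalization
        self.positive_class = positive_class
        self.random_state = random_state

    def fit(self, t: FeatureTable, y=None):
        if len(t.feature_names) == 0:
            raise ConfigurationError("cannot train on an empty feature table")
        y01, pos = encode_labels(t.labels, self.positive_class)
        if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
            raise DegenerateSampleError("each class needs at least 2 samples")
        self.positive_class_ = pos
        classes = sorted(t.labels.unique())
        self.negative_class_ = [c for c in classes if c != pos][0]
        self.feature_names_ = list(t.feature_names)
        self.scaler_ = FeatureScaler(method=self.normalization).fit(t)
        Xs = self.scaler_.transform(t)
        self.estimator_ = _make_estimator(self.algorithm, self.random_state)
        self.estimator_.fit(Xs.data.to_numpy(dtype=float), y01)
        return self

    def _align(self, t: FeatureTable, fill_missing_motifs: bool = False) -> FeatureTable:
        """Align columns by name to the training contract."""
        missing = [f for f in self.feature_names_ if f not in t.data.columns]
        if missing:
            motif_missing = [f for f in missing if f.startswith("motif")]
            hard_missing = [f for f in missing if not f.startswith("motif")]
            if hard_missing or not fill_missing_motifs:
                raise ContractError(
                    f"feature table lacks model features: {missing}"
                )
            warnings.warn(
                f"motif features absent in the test repertoire zero-filled: "
                f"{motif_missing}", stacklevel=3,
            )
        data = t.data.reindex(columns=self.feature_names_, fill_value=0.0)
        return FeatureTable(data, t.labels.copy(),
                            {c: t.provenance.get(c, "unknown") for c in data.columns},
                            t.label_column_name)

    def _matrix(self, t: FeatureTable, fill_missing_motifs=False) -> np.ndarray:
        aligned = self._align(t, fill_missing_motifs=fill_missing_motifs)
        return self.scaler_.transform(aligned).data.to_numpy(dtype=float)

    def predict(self, t: FeatureTable, fill_missing_motifs: bool = False):
        y01 = self.estimator_.predict(self._matrix(t, fill_missing_motifs))
        return np.where(y01 == 1, self.positive_class_, self.negative_class_)

    def predict_proba(self, t: FeatureTable, fill_missing_motifs: bool = False):
        """Positive-class probability per sample."""
        return self.estimator_.predict_proba(
            self._matrix(t, fill_missing_motifs))[:, 1]


def train(t: FeatureTable, algorithm: str = "DT", positive_class=None,
          seed: int = 0, normalization: str = "none") -> RepertoireClassifier:
    """Fit one classifier on a feature table; deterministic given the seed."""
    return RepertoireClassifier(
        algorithm=algorithm, normalization=normalization,
        positive_class=positive_class, random_state=seed,
    ).fit(t)


def cross_validate(t: FeatureTable, algorithm: str = "DT",
                   k_folds: int = DEFAULT_K_FOLDS, repeats: int = DEFAULT_REPEATS,
                   seed: int = 0, normalization: str = "none",
                   positive_class=None, leakage_safe: bool = True) -> EvaluationReport:
    """Repeated stratified k-fold evaluation (default threefold, 100 repeats).

    Folds are reshuffled each repeat from the seed.  Normalization is
    refitted inside each training fold (``leakage_safe=True``, default);
    ``leakage_safe=False`` reproduces a normalize-before-split flow.  The
    confusion matrix is summed over every fold of every repeat, so its total
    equals ``n_samples * repeats``.
    """
    y01, pos = encode_labels(t.labels, positive_class)
    class_min = min((y01 == 0).sum(), (y01 == 1).sum())
    if class_min < k_folds:
        raise DegenerateSampleError(
            f"smallest class has {class_min} samples < k_folds={k_folds}; "
            "use a smaller k"
        )
    work = t
    norm_inner = normalization
    if not leakage_safe and normalization != "none":
        work = FeatureScaler(method=normalization).fit(t).transform(t)
        norm_inner = "none"

    per_fold = {m: [] for m in METRIC_NAMES}
    cm_total = np.zeros((2, 2), dtype=int)
    idx = np.arange(len(work.sample_ids))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=(seed + r) % (2**31 - 1))
        for train_idx, test_idx in skf.split(idx, y01):
            t_train = _subset(work, train_idx)
            t_test = _subset(work, test_idx)
            model = RepertoireClassifier(
                algorithm=algorithm, normalization=norm_inner,
                positive_class=pos, random_state=seed,
            ).fit(t_train)
            y_pred = model.predict(t_test)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y_score = model.predict_proba(t_test)
                fold = metrics(list(t_test.labels), list(y_pred), y_score,
                               positive_class=pos)
            for m in METRIC_NAMES:
                per_fold[m].append(fold[m])
            cm_total += fold["confusion_matrix"]
    means = {m: float(np.nanmean(per_fold[m])) for m in METRIC_NAMES}
    stds = {m: float(np.nanstd(per_fold[m])) for m in METRIC_NAMES}
    neg = [c for c in sorted(t.labels.unique()) if c != pos][0]
    return EvaluationReport(
        means=means, stds=stds, confusion_matrix=cm_total,
        scheme={"k_folds": k_folds, "repeats": repeats, "seed": seed,
                "algorithm": algorithm, "normalization": normalization,
                "leakage_safe": leakage_safe},
        class_names=(str(neg), str(pos)),
    )


def evaluate_external(model: RepertoireClassifier,
                      t_test: FeatureTable) -> EvaluationReport:
    """Apply a frozen model to an independent cohort; nothing is refitted.

    Columns are aligned by name; motif columns absent from the test
    repertoire are zero-filled with a warning, any other missing feature is
    a contract error.  A model whose selected features include t-SNE axes
    cannot be validated externally (t-SNE has no out-of-sample map).
    """
    if any(name.startswith("TSNE") for name in model.feature_names_):
        raise NonTransferableFeatureError(
            "model uses t-SNE features, which cannot be mapped onto an "
            "external cohort"
        )
    y_pred = model.predict(t_test, fill_missing_motifs=True)
    y_score = model.predict_proba(t_test, fill_missing_motifs=True)
    result = metrics(list(t_test.labels), list(y_pred), y_score,
                     positive_class=model.positive_class_)
    means = {m: float(result[m]) for m in METRIC_NAMES}
    return EvaluationReport(
        means=means, stds={m: 0.0 for m in METRIC_NAMES},
        confusion_matrix=result["confusion_matrix"],
        scheme={"mode": "external", "algorithm": model.algorithm,
                "n_test": len(t_test.sample_ids)},
        class_names=(str(model.negative_class_), str(model.positive_class_)),
    )


def _subset(t: FeatureTable, idx) -> FeatureTable:
    data = t.data.iloc[idx]
    return FeatureTable(data, t.labels.iloc[idx], dict(t.provenance),
                        t.label_column_name)
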