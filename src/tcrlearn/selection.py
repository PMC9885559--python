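"""Feature ranking by predictive power.

Four rankers are provided: Pearson correlation with the label (univariate
filter), mRMR (greedy minimum-redundancy maximum-relevance, FCQ variant),
Ridge (|coefficient| of an L2-penalized linear fit on standardized
features), and gradient-boosted-tree gain importance (XGBoost).

Rank encoding, shared by all methods: 0 = not selected, 1 = most
predictive, 2 = second, ...  The default number of features to select is
the anti-overfitting cap ``min(class sizes) - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import f_classif
from sklearn.linear_model import Ridge

from .errors import ConfigurationError, DegenerateSampleError, EmptySelectionError
from .io import FeatureTable

RANKING_METHODS = ("pearson", "mrmr", "ridge", "xgboost")

#: redundancy floor of the mRMR quotient, guarding division by ~0
MRMR_REDUNDANCY_FLOOR = 1e-6


def max_features(labels) -> int:
    """Overfitting cap on the number of selected features:
    the minimum class size minus one."""
    counts = pd.Series(list(labels)).value_counts()
    if len(counts) < 2:
        raise DegenerateSampleError("need at least two classes")
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise DegenerateSampleError(f"classes with fewer than 2 samples: {small}")
    return int(counts.min()) - 1


def encode_labels(labels, positive_class=None):
    """Encode binary labels as 0/1; positive class defaults to the second
    label in sorted order."""
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ConfigurationError(f"expected exactly 2 classes, found {classes}")
    if positive_class is None:
        positive_class = classes[1]
    elif positive_class not in classes:
        raise ConfigurationError(
            f"positive class {positive_class!r} not among labels {classes}"
        )
    return (labels == positive_class).to_numpy(dtype=int), positive_class


def _cap_k(k, n_features: int) -> int:
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if k > n_features:
        warnings.warn(
            f"k={k} exceeds the {n_features} available features; capped",
            stacklevel=3,
        )
        return n_features
    return int(k)


def _ranks_from_order(order, names, k: int) -> pd.Series:
    ranks = pd.Series(0, index=list(names), dtype=int)
    for r, name in enumerate(order[:k], start=1):
        ranks[name] = r
    return ranks


class _BaseRanker(BaseEstimator):
    """Shared fit plumbing: subclasses produce a full preference order."""

    def __init__(self, k=None, positive_class=None):
        self.k = k
        self.positive_class = positive_class

    def fit(self, t: FeatureTable, y=None):
        y01, pos = encode_labels(t.labels, self.positive_class)
        k = self.k if self.k is not None else max_features(t.labels)
        k = _cap_k(k, len(t.feature_names))
        order, scores = self._order(t.data, y01, k)
        self.positive_class_ = pos
        self.k_selected_ = k
        self.scores_ = scores
        self.ranking_ = self._encode(order, t.feature_names, k, scores)
        return self

    def _encode(self, order, names, k, scores) -> pd.Series:
        return _ranks_from_order(order, names, k)

    def transform(self, t: FeatureTable) -> FeatureTable:
        selected = self.ranking_[self.ranking_ > 0].sort_values().index
        if len(selected) == 0:
            raise EmptySelectionError("no feature was selected")
        data = t.data[list(selected)]
        return FeatureTable(data, t.labels.copy(),
                            {c: t.provenance.get(c, "unknown") for c in data.columns},
                            t.label_column_name)


def _abs_pearson_with_label(data: pd.DataFrame, y01: np.ndarray) -> pd.Series:
    X = data.to_numpy(dtype=float)
    y = y01 - y01.mean()
    xc = X - X.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ y / np.where(denom == 0, 1, denom), 0.0)
    return pd.Series(np.abs(r), index=data.columns)


class PearsonRanker(_BaseRanker):
    """Rank by |Pearson correlation| of each feature with the 0/1 label.

    Considers one feature at a time: two near-duplicate informative
    features both rank at the top (the method's known weakness)."""

    def _order(self, data, y01, k):
        scores = _abs_pearson_with_label(data, y01)
        order = sorted(scores.index, key=lambda f: (-scores[f], f))
        return order, scores


class MRMRRanker(_BaseRanker):
    """Greedy minimum-redundancy maximum-relevance selection.

    Relevance = one-way F-statistic of the feature against the class;
    redundancy = mean |Pearson r| with the already-selected features.
    The default FCQ scheme maximizes relevance / redundancy; MID
    (relevance - redundancy) is available via ``scheme="MID"``.
    """

    def __init__(self, k=None, positive_class=None, scheme: str = "FCQ"):
        super().__init__(k=k, positive_class=positive_class)
        self.scheme = scheme

    def _order(self, data, y01, k):
        if self.scheme not in ("FCQ", "MID"):
            raise ConfigurationError(f"unknown mRMR scheme {self.scheme!r}")
        X = data.to_numpy(dtype=float)
        names = list(data.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, _ = f_classif(X, y01)
        relevance = pd.Series(np.nan_to_num(F, nan=0.0), index=names)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(np.nan_to_num(np.corrcoef(X, rowvar=False), nan=0.0))
        corr_df = pd.DataFrame(np.atleast_2d(corr), index=names, columns=names)
        selected: list = []
        remaining = list(names)
        while remaining and len(selected) < k:
            if not selected:
                scores = relevance[remaining]
            else:
                red = corr_df.loc[remaining, selected].mean(axis=1)
                if self.scheme == "FCQ":
                    scores = relevance[remaining] / red.clip(lower=MRMR_REDUNDANCY_FLOOR)
                else:
                    scores = relevance[remaining] - red
            best = sorted(remaining, key=lambda f: (-scores[f], f))[0]
            selected.append(best)
            remaining.remove(best)
        return selected, relevance


class RidgeRanker(_BaseRanker):
    """Rank by |coefficient| of an L2-penalized linear model of the 0/1
    label on standardized features (penalty weight ``alpha``, default 1.0)."""

    def __init__(self, k=None, positive_class=None, alpha: float = 1.0):
        super().__init__(k=k, positive_class=positive_class)
        self.alpha = alpha

    def _order(self, data, y01, k):
        X = data.to_numpy(dtype=float)
        sd = X.std(axis=0)
        Xs = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        model = Ridge(alpha=self.alpha)
        model.fit(Xs, y01)
        scores = pd.Series(np.abs(model.coef_), index=data.columns)
        order = sorted(scores.index, key=lambda f: (-scores[f], f))
        return order, scores


class GradientBoostRanker(_BaseRanker):
    """Rank by gain importance of seeded gradient-boosted trees (XGBoost).

    Features never used in any split have zero importance and rank 0 even
    inside the top-k."""

    def __init__(self, k=None, positive_class=None, random_state: int = 0,
                 n_estimators: int = 100, max_depth: int = 3,
                 learning_rate: float = 0.3):
        super().__init__(k=k, positive_class=positive_class)
        self.random_state = random_state
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate

    def _order(self, data, y01, k):
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            importance_type="gain",
            verbosity=0,
        )
        model.fit(data.to_numpy(dtype=float), y01)
        scores = pd.Series(model.feature_importances_, index=data.columns)
        order = sorted(scores.index, key=lambda f: (-scores[f], f))
        return order, scores

    def _encode(self, order, names, k, scores):
        ranks = pd.Series(0, index=list(names), dtype=int)
        r = 1
        for name in order[:k]:
            if scores[name] > 0:
                ranks[name] = r
                r += 1
        return ranks


_RANKERS = {
    "pearson": PearsonRanker,
    "mrmr": MRMRRanker,
    "ridge": RidgeRanker,
    "xgboost": GradientBoostRanker,
}


@dataclass
class FeatureRanking:
    """Per-method integer ranks over all features (0 = unselected)."""

    table: pd.DataFrame  # rows = features, columns = methods, int cells
    k_selected: dict

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def ranks(self, method: str) -> pd.Series:
        if method not in self.table.columns:
            raise ConfigurationError(
                f"no ranking for method {method!r}; have {list(self.table.columns)}"
            )
        return self.table[method]


def rank_pearson(t, k=None, positive_class=None):
    return PearsonRanker(k=k, positive_class=positive_class).fit(t)


def rank_mrmr(t, k=None, positive_class=None, scheme="FCQ"):
    return MRMRRanker(k=k, positive_class=positive_class, scheme=scheme).fit(t)


def rank_ridge(t, k=None, positive_class=None, alpha=1.0):
    return RidgeRanker(k=k, positive_class=positive_class, alpha=alpha).fit(t)


def rank_xgboost(t, k=None, positive_class=None, seed=0):
    return GradientBoostRanker(k=k, positive_class=positive_class,
                               random_state=seed).fit(t)


def rank_features(t: FeatureTable, methods=RANKING_METHODS, k=None,
                  positive_class=None, seed: int = 0) -> FeatureRanking:
    """Run several rankers and assemble the downloadable rank table."""
    cols, ks = {}, {}
    for m in methods:
        if m not in _RANKERS:
            raise ConfigurationError(
                f"unknown ranking method {m!r}; choose from {RANKING_METHODS}"
            )
        kwargs = {"k": k, "positive_class": positive_class}
        if m == "xgboost":
            kwargs["random_state"] = seed
        est = _RANKERS[m](**kwargs).fit(t)
        cols[m] = est.ranking_
        ks[m] = est.k_selected_
    table = pd.DataFrame(cols, index=t.feature_names).astype(int)
    table.index.name = "feature"
    return FeatureRanking(table=table, k_selected=ks)


def select(t: FeatureTable, ranking: FeatureRanking, method: str,
           k=None) -> FeatureTable:
    """Restrict ``t`` to the features ranked 1..k by ``method``,
    columns ordered by rank."""
    ranks = ranking.ranks(method)
    if k is None:
        k = int(ranks.max())
    chosen = ranks[(ranks >= 1) & (ranks <= k)].sort_values().index
    if len(chosen) == 0:
        raise EmptySelectionError(f"method {method!r} selected no features")
    data = t.data[list(chosen)]
    return FeatureTable(data, t.labels.copy(),
                        {c: t.provenance.get(c, "unknown") for c in data.columns},
                        t.label_column_name)
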