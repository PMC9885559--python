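"""Low-dimensional per-sample coordinates from the raw count matrix.

Six reduction methods are exposed — PCA, t-SNE, UMAP, ICA, SVD and ISOMAP —
each producing named feature columns (``PC1``/``PC2``, ``TSNE1``, ``UMAP1``,
``IC1``, ``SVD1``, ``ISO1``, ...).  All stochastic methods take an explicit
seed, recorded on the fitted transformer.  t-SNE has no out-of-sample map:
its coordinates cannot be transferred to an external validation cohort, and
``transform`` on unseen samples raises accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FastICA, TruncatedSVD
from sklearn.manifold import TSNE, Isomap

from .errors import ConfigurationError, NonTransferableFeatureError
from .io import FeatureTable, RepertoireMatrix

METHODS = ("PCA", "TSNE", "UMAP", "ICA", "SVD", "ISOMAP")

_PREFIX = {"PCA": "PC", "TSNE": "TSNE", "UMAP": "UMAP", "ICA": "IC",
           "SVD": "SVD", "ISOMAP": "ISO"}

#: methods whose fitted transformer maps unseen samples into the same space
TRANSFERABLE = ("PCA", "UMAP", "ICA", "SVD", "ISOMAP")


class EmbeddingFeatures(BaseEstimator, TransformerMixin):
    """Dimensionality-reduction feature transformer over clonotype counts.

    Parameters
    ----------
    method : {"PCA", "TSNE", "UMAP", "ICA", "SVD", "ISOMAP"}
    n_components : int, default 2 (at most 3)
    random_state : int, default 42
        Seed for every stochastic method; recorded on the fitted object.
    params : dict, optional
        Extra method hyperparameters (``perplexity``, ``n_neighbors``, ...)
        forwarded to the underlying library estimator.
    """

    def __init__(self, method: str = "PCA", n_components: int = 2,
                 random_state: int = 42, params: dict | None = None):
        self.method = method
        self.n_components = n_components
        self.random_state = random_state
        self.params = params

    def _check(self, X: RepertoireMatrix):
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown embedding method {self.method!r}; choose from {METHODS}"
            )
        if not 1 <= self.n_components <= 3:
            raise ConfigurationError("n_components must be 1, 2 or 3")
        if self.n_components >= X.n_samples:
            raise ConfigurationError(
                f"n_components={self.n_components} must be < n_samples={X.n_samples}"
            )
        if X.n_samples < 3:
            raise ConfigurationError("embedding requires at least 3 samples")

    def _make_reducer(self, n_samples: int):
        p = dict(self.params or {})
        k, seed = self.n_components, self.random_state
        if self.method == "PCA":
            return PCA(n_components=k, random_state=seed, **p)
        if self.method == "ICA":
            p.setdefault("max_iter", 1000)
            return FastICA(n_components=k, random_state=seed, **p)
        if self.method == "SVD":
            return TruncatedSVD(n_components=k, random_state=seed, **p)
        if self.method == "ISOMAP":
            p.setdefault("n_neighbors", min(5, n_samples - 1))
            return Isomap(n_components=k, **p)
        if self.method == "TSNE":
            p.setdefault("perplexity", min(30.0, max(1.0, (n_samples - 1) / 3)))
            p.setdefault("init", "pca")
            return TSNE(n_components=k, random_state=seed, **p)
        if self.method == "UMAP":
            import umap  # deferred: numba compilation makes this import heavy

            p.setdefault("n_neighbors", min(15, n_samples - 1))
            return umap.UMAP(n_components=k, random_state=seed, **p)
        raise AssertionError(self.method)

    def fit(self, X: RepertoireMatrix, y=None):
        self._check(X)
        counts = np.asarray(X.counts, dtype=float)
        self.reducer_ = self._make_reducer(X.n_samples)
        self.feature_names_out_ = [
            f"{_PREFIX[self.method]}{i + 1}" for i in range(self.n_components)
        ]
        self.fitted_coords_ = self.reducer_.fit_transform(counts)
        self.fitted_sample_ids_ = list(X.sample_ids)
        self._fitted_counts = counts
        self.transferable_ = self.method in TRANSFERABLE
        return self

    def transform(self, X: RepertoireMatrix) -> FeatureTable:
        same_cohort = (
            list(X.sample_ids) == self.fitted_sample_ids_
            and np.array_equal(np.asarray(X.counts, dtype=float),
                               self._fitted_counts)
        )
        if same_cohort:
            coords = self.fitted_coords_
        elif not self.transferable_:
            raise NonTransferableFeatureError(
                "t-SNE has no out-of-sample mapping; its coordinates cannot be "
                "computed for samples outside the fitted cohort"
            )
        else:
            coords = self.reducer_.transform(np.asarray(X.counts, dtype=float))
        data = pd.DataFrame(np.asarray(coords, dtype=float),
                            index=X.sample_ids, columns=self.feature_names_out_)
        return FeatureTable(
            data=data,
            labels=X.labels.copy(),
            provenance={c: "embedding" for c in data.columns},
            label_column_name=X.label_column_name,
        )


def embed(m: RepertoireMatrix, method: str = "PCA", n_components: int = 2,
          random_state: int = 42, params: dict | None = None):
    """Fit one reduction method on ``m`` and return ``(FeatureTable, transformer)``.

    The transformer maps external-validation samples into the same space for
    every method except t-SNE, for which ``None`` is returned.
    """
    est = EmbeddingFeatures(method=method, n_components=n_components,
                            random_state=random_state, params=params).fit(m)
    table = est.transform(m)
    return table, (est if est.transferable_ else None)
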