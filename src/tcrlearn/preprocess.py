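"""Feature-table normalization and assembly.

Three per-feature affine normalizations are offered, applied to the derived
feature table (not the raw counts):

* ``standard`` — mean 0, standard deviation 1
* ``minmax``   — linear map of the training range onto [-1, +1]
* ``robust``   — (x - median) / IQR, with linear-interpolation (type-7)
  quartiles

Statistics are learned from training data only and frozen, so the identical
affine map applies to unseen (external-validation) data; values outside the
training range map outside [-1, 1] without clipping.  Constant features map
to 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, ContractError
from .io import FeatureTable

METHODS = ("standard", "minmax", "robust", "none")


@dataclass
class NormalizationParams:
    """Frozen per-feature affine statistics: ``x -> (x - center) / scale``
    (for minmax an extra [-1,1] range map is folded into center/scale)."""

    method: str
    feature_names: list
    center: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray


class FeatureScaler(BaseEstimator, TransformerMixin):
    """Sklearn-style scaler over FeatureTable columns with a frozen affine map."""

    def __init__(self, method: str = "standard"):
        self.method = method

    def fit(self, X: FeatureTable, y=None):
        if self.method not in METHODS:
            raise ConfigurationError(
                f"unknown normalization {self.method!r}; choose from {METHODS}"
            )
        vals = X.data.to_numpy(dtype=float)
        n = vals.shape[0]
        if self.method in ("standard", "robust") and n < 2:
            raise ConfigurationError(
                f"{self.method} normalization requires at least 2 samples"
            )
        constant = vals.max(axis=0) == vals.min(axis=0)
        if self.method == "none":
            center = np.zeros(vals.shape[1])
            scale = np.ones(vals.shape[1])
            constant = np.zeros(vals.shape[1], dtype=bool)
        elif self.method == "standard":
            center = vals.mean(axis=0)
            scale = vals.std(axis=0)  # population sd (ddof=0)
        elif self.method == "minmax":
            lo, hi = vals.min(axis=0), vals.max(axis=0)
            # (x - lo)/(hi - lo) * 2 - 1  ==  (x - (lo+hi)/2) / ((hi-lo)/2)
            center = (lo + hi) / 2.0
            scale = (hi - lo) / 2.0
        else:  # robust
            q1, med, q3 = np.percentile(vals, [25, 50, 75], axis=0)
            center = med
            scale = q3 - q1
        if self.method != "none" and constant.any():
            names = [c for c, m in zip(X.data.columns, constant) if m]
            warnings.warn(f"constant features mapped to 0: {names}", stacklevel=2)
        scale = np.where(scale == 0, 1.0, scale)
        self.params_ = NormalizationParams(
            method=self.method,
            feature_names=list(X.data.columns),
            center=center,
            scale=scale,
            constant_mask=constant,
        )
        return self

    def transform(self, X: FeatureTable) -> FeatureTable:
        p = self.params_
        if list(X.data.columns) != p.feature_names:
            missing = set(p.feature_names) - set(X.data.columns)
            extra = set(X.data.columns) - set(p.feature_names)
            if missing or extra:
                raise ContractError(
                    f"feature-name mismatch; missing: {sorted(missing)}, "
                    f"extra: {sorted(extra)}"
                )
            X = FeatureTable(X.data[p.feature_names], X.labels,
                             dict(X.provenance), X.label_column_name)
        vals = (X.data.to_numpy(dtype=float) - p.center) / p.scale
        vals[:, p.constant_mask] = 0.0
        data = pd.DataFrame(vals, index=X.data.index, columns=p.feature_names)
        return FeatureTable(data, X.labels.copy(), dict(X.provenance),
                            X.label_column_name)


def normalize(t: FeatureTable, method: str = "standard"):
    """Fit the requested normalization on ``t`` and apply it.

    Returns ``(normalized_table, params)``; ``params`` reapplies the
    identical affine map to unseen data via :func:`apply_normalization`.
    """
    scaler = FeatureScaler(method=method).fit(t)
    return scaler.transform(t), scaler.params_


def apply_normalization(t: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Apply frozen normalization statistics to ``t``; never refits."""
    scaler = FeatureScaler(method=params.method)
    scaler.params_ = params
    return scaler.transform(t)


def merge_features(tables) -> FeatureTable:
    """Column-wise concatenation of feature tables sharing samples and labels."""
    tables = list(tables)
    if not tables:
        raise ContractError("merge_features requires at least one table")
    first = tables[0]
    names: list = []
    for t in tables:
        if list(t.data.index) != list(first.data.index):
            raise ContractError("sample_ids differ between feature tables")
        if not t.labels.reset_index(drop=True).equals(
                first.labels.reset_index(drop=True)):
            raise ContractError("labels differ between feature tables")
        names.extend(t.data.columns)
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ContractError(f"duplicate feature names across tables: {dups}")
    data = pd.concat([t.data for t in tables], axis=1)
    prov: dict = {}
    for t in tables:
        prov.update(t.provenance)
    return FeatureTable(data, first.labels.copy(), prov, first.label_column_name)
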