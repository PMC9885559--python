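"""Ecological diversity indices of clone-abundance distributions.

Each index is computed per sample from the relative abundances
``p_i = c_i / N`` of the clonotypes observed (nonzero count) in that sample:

* richness ``S`` — number of distinct clonotypes
* Shannon ``H = -sum p_i log p_i`` (natural log by default)
* Simpson dominance ``lambda = sum p_i^2`` and its inverse ``1/lambda``
* Pielou evenness ``J = H / log S`` and clonality ``1 - J``
* Hill numbers ``qD = (sum p_i^q)^(1/(1-q))``, with ``1D = exp(H)``
* Gini coefficient of the abundance distribution

The ``q``-profile of Hill numbers interpolates the classical indices:
``0D`` is richness, ``1D`` the exponential Shannon, ``2D`` the inverse
Simpson; ``qD`` is non-increasing in ``q``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DegenerateSampleError
from .io import FeatureTable, RepertoireMatrix

DEFAULT_HILL_ORDERS = (0.0, 1.0, 2.0, 3.0)


def _proportions(counts) -> np.ndarray:
    """Relative abundances of the observed (nonzero) clones of one sample."""
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or (c < 0).any() or not np.isfinite(c).all():
        raise DegenerateSampleError("invalid abundance vector")
    c = c[c > 0]
    if c.size == 0:
        raise DegenerateSampleError("sample has no reads (all counts zero)")
    return c / c.sum()


def richness(counts) -> int:
    """Number of distinct clonotypes with nonzero count, ``S``."""
    return int(_proportions(counts).size)


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy ``H = -sum p_i log p_i``; nats by default."""
    p = _proportions(counts)
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def simpson(counts) -> float:
    """Simpson dominance ``lambda = sum p_i^2`` (probability that two random
    reads share a clonotype; higher = more clonal)."""
    p = _proportions(counts)
    return float((p * p).sum())


def inverse_simpson(counts) -> float:
    """``1 / lambda``, the effective number of dominant clonotypes."""
    return 1.0 / simpson(counts)


def pielou(counts, base: float | None = None) -> float:
    """Pielou evenness ``J = H / log S``; by convention ``J = 0`` for a
    monoclonal sample (``S = 1``), making clonality maximal there."""
    p = _proportions(counts)
    if p.size == 1:
        return 0.0
    return shannon(counts, base=base) / (np.log(p.size) / (1.0 if base is None else np.log(base)))


def one_minus_pielou(counts, base: float | None = None) -> float:
    """Clonality, ``1 - J``."""
    return 1.0 - pielou(counts, base=base)


def hill(counts, q: float) -> float:
    """Hill number of order ``q``: effective clonotype count ``qD``.

    ``q = 1`` is evaluated by its limit form ``exp(H)``.
    """
    if q < 0:
        raise ConfigurationError(f"Hill order q must be >= 0, got {q}")
    p = _proportions(counts)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def gini(counts) -> float:
    """Gini coefficient of the observed clone proportions.

    ``G = sum_ij |p_i - p_j| / (2 S^2 pbar)`` with ``pbar = 1/S``;
    0 = perfectly even, -> 1 for extreme clonal dominance.
    """
    p = np.sort(_proportions(counts))
    s = p.size
    if s == 1:
        return 0.0
    # sorted-rank identity for the mean absolute difference
    i = np.arange(1, s + 1)
    return float((2.0 * (i * p).sum() - (s + 1)) / s)


class DiversityFeatures(BaseEstimator, TransformerMixin):
    """Transformer computing the diversity feature row per sample.

    Parameters
    ----------
    hill_orders : sequence of float, default (0, 1, 2, 3)
        Orders ``q`` of the Hill-number profile.
    base : float or None
        Logarithm base for Shannon/Pielou; ``None`` = natural log.
    """

    def __init__(self, hill_orders=DEFAULT_HILL_ORDERS, base=None):
        self.hill_orders = hill_orders
        self.base = base

    def fit(self, X: RepertoireMatrix, y=None):
        for q in self.hill_orders:
            if q < 0:
                raise ConfigurationError(f"Hill order q must be >= 0, got {q}")
        self.feature_names_out_ = [
            "richness", "shannon", "simpson", "inverse_simpson",
            "pielou", "one_minus_pielou",
        ] + [f"hill_q{_fmt_q(q)}" for q in self.hill_orders] + ["gini"]
        return self

    def transform(self, X: RepertoireMatrix) -> FeatureTable:
        rows = []
        for i, sid in enumerate(X.sample_ids):
            c = X.counts[i]
            if not (np.asarray(c) > 0).any():
                raise DegenerateSampleError(f"sample {sid!r} has no reads")
            row = {
                "richness": richness(c),
                "shannon": shannon(c, base=self.base),
                "simpson": simpson(c),
                "inverse_simpson": inverse_simpson(c),
                "pielou": pielou(c, base=self.base),
                "one_minus_pielou": one_minus_pielou(c, base=self.base),
            }
            for q in self.hill_orders:
                row[f"hill_q{_fmt_q(q)}"] = hill(c, q)
            row["gini"] = gini(c)
            rows.append(row)
        data = pd.DataFrame(rows, index=X.sample_ids)[self.feature_names_out_]
        return FeatureTable(
            data=data,
            labels=X.labels.copy(),
            provenance={c: "diversity" for c in data.columns},
            label_column_name=X.label_column_name,
        )


def _fmt_q(q) -> str:
    return str(int(q)) if float(q).is_integer() else str(q)


def diversity_features(m: RepertoireMatrix, hill_orders=DEFAULT_HILL_ORDERS,
                       base=None) -> FeatureTable:
    """One diversity feature row per sample; labels carried through."""
    return DiversityFeatures(hill_orders=hill_orders, base=base).fit(m).transform(m)
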