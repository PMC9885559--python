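"""Contiguous amino-acid k-mer (motif) frequency profiles per sample.

For each sample and each k (default 2, 3, 4), every length-k window of every
clonotype sequence is counted — weighted by the clone's count in
``abundance`` mode, or once per distinct sequence in ``presence`` mode —
and the counts are normalized to frequencies that sum to 1 within each k.
A 2-mer and a 4-mer column are therefore on separate denominators.
Columns are the literal k-mer strings prefixed ``motif2_``/``motif3_``/
``motif4_``, lexicographically ordered within each k.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .io import FeatureTable, RepertoireMatrix

DEFAULT_KS = (2, 3, 4)


def kmer_counts(sequence: str, k: int) -> dict:
    """Counts of all ``len(sequence) - k + 1`` overlapping k-mer windows;
    empty when the sequence is shorter than ``k``."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    return dict(Counter(sequence[i:i + k] for i in range(len(sequence) - k + 1)))


class MotifFeatures(BaseEstimator, TransformerMixin):
    """Transformer computing per-sample k-mer frequency columns.

    Parameters
    ----------
    ks : sequence of int, default (2, 3, 4)
        Window lengths.
    weighting : {"abundance", "presence"}
        ``abundance`` multiplies each sequence's window counts by its clone
        count before normalizing; ``presence`` weights every distinct
        observed sequence equally.
    min_frequency : float or None
        Optional filter dropping columns whose frequency never reaches this
        value in any sample (default: keep all observed k-mers).

    ``fit`` learns the column union over the fitted matrix; ``transform``
    zero-fills k-mers of new samples that were never seen at fit time.
    """

    def __init__(self, ks=DEFAULT_KS, weighting: str = "abundance",
                 min_frequency: float | None = None):
        self.ks = ks
        self.weighting = weighting
        self.min_frequency = min_frequency

    def fit(self, X: RepertoireMatrix, y=None):
        if not self.ks:
            raise ConfigurationError("ks must be non-empty")
        if self.weighting not in ("abundance", "presence"):
            raise ConfigurationError(f"unknown weighting {self.weighting!r}")
        table = self._profile(X)
        if self.min_frequency:
            table = table.loc[:, table.max(axis=0) >= self.min_frequency]
        self.feature_names_out_ = list(table.columns)
        return self

    def transform(self, X: RepertoireMatrix) -> FeatureTable:
        table = self._profile(X).reindex(columns=self.feature_names_out_, fill_value=0.0)
        return FeatureTable(
            data=table,
            labels=X.labels.copy(),
            provenance={c: "motif" for c in table.columns},
            label_column_name=X.label_column_name,
        )

    def _profile(self, X: RepertoireMatrix) -> pd.DataFrame:
        rows = []
        for i in range(X.n_samples):
            row: dict[str, float] = {}
            for k in self.ks:
                acc: Counter = Counter()
                for seq, cnt in zip(X.clonotypes, X.counts[i]):
                    if cnt <= 0:
                        continue
                    w = cnt if self.weighting == "abundance" else 1
                    for kmer, n in kmer_counts(seq, k).items():
                        acc[kmer] += w * n
                total = sum(acc.values())
                if total > 0:
                    for kmer, n in acc.items():
                        row[f"motif{k}_{kmer}"] = n / total
            rows.append(row)
        df = pd.DataFrame(rows, index=X.sample_ids).fillna(0.0)
        return df[sorted(df.columns)]


def motif_features(m: RepertoireMatrix, ks=DEFAULT_KS, weighting: str = "abundance",
                   min_frequency: float | None = None) -> FeatureTable:
    """Per-sample motif frequency table over the k-mers observed anywhere in ``m``."""
    est = MotifFeatures(ks=ks, weighting=weighting, min_frequency=min_frequency)
    return est.fit(m).transform(m)
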