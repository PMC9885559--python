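"""Reading the repertoire CSV dialect and writing every downloadable artifact.

The sole input is a CSV (optionally a single-member ZIP) whose rows are
repertoire samples, whose columns are clonotype CDR3 amino-acid strings plus
one label column, and whose cells are non-negative clone counts.
"""

from __future__ import annotations

import io as _stdio
import pickle
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ModelFormatError, ValidationError
from .version import __version__

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: schema version of the model container file
MODEL_FORMAT_VERSION = 1


@dataclass
class RepertoireMatrix:
    """Samples x clonotype-counts matrix with one categorical label per sample.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers (row names).
    clonotypes : list of str
        Unique amino-acid CDR3 strings (column names), input order preserved.
    counts : ndarray of shape (n_samples, n_clonotypes)
        Non-negative integer clone counts.
    labels : pandas.Series
        One label per sample, indexed by ``sample_ids``.
    label_column_name : str
        Name of the label column in the source table.
    """

    sample_ids: list = field(default_factory=list)
    clonotypes: list = field(default_factory=list)
    counts: np.ndarray = None
    labels: pd.Series = None
    label_column_name: str = "label"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.clonotypes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.clonotypes)} clonotypes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if len(set(self.clonotypes)) != len(self.clonotypes):
            raise ValidationError("clonotypes are not unique")
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(list(self.labels), index=self.sample_ids)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValidationError(f"missing labels for samples {missing}")
        _validate_counts(self.counts)
        odd = sorted({c for s in self.clonotypes for c in s} - AMINO_ACIDS)
        if any(len(s) == 0 for s in self.clonotypes):
            raise ValidationError("empty clonotype string")
        if odd:
            warnings.warn(
                f"clonotype sequences contain non-amino-acid characters: {odd}",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    def to_frame(self) -> pd.DataFrame:
        """Return the on-disk layout: counts plus the label column."""
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.clonotypes)
        df[self.label_column_name] = self.labels.values
        return df

    def sample_counts(self, sample_id) -> pd.Series:
        """Clone counts of one sample over all clonotype columns."""
        i = self.sample_ids.index(sample_id)
        return pd.Series(self.counts[i], index=self.clonotypes)


@dataclass
class FeatureTable:
    """Samples x named numeric features plus labels; the interchange object
    between all pipeline stages.

    ``provenance`` tags each column with the feature dimension it came from
    (``diversity`` | ``network`` | ``motif`` | ``embedding``).
    """

    data: pd.DataFrame
    labels: pd.Series
    provenance: dict = field(default_factory=dict)
    label_column_name: str = "label"

    def __post_init__(self):
        if not self.data.index.equals(self.labels.index):
            raise ValidationError("feature rows and labels are not aligned")
        if self.data.columns.duplicated().any():
            dups = list(self.data.columns[self.data.columns.duplicated()])
            raise ValidationError(f"duplicate feature names: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("feature table contains non-finite values")
        for col in self.data.columns:
            self.provenance.setdefault(col, "unknown")

    @property
    def feature_names(self) -> list:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df[self.label_column_name] = self.labels.values
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "label",
                   provenance: dict | None = None) -> "FeatureTable":
        if label_column not in df.columns:
            raise ConfigurationError(
                f"label column {label_column!r} not found; available: {list(df.columns)}"
            )
        labels = df[label_column]
        data = df.drop(columns=[label_column]).astype(float)
        return cls(data=data, labels=labels, provenance=dict(provenance or {}),
                   label_column_name=label_column)


def _validate_counts(counts: np.ndarray) -> None:
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("counts are not numeric")
    bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.floor(arr))
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"negative or non-integral count at row {r}, column {c}: {arr[r, c]!r}"
        )


def _read_csv_payload(path: Path) -> pd.DataFrame:
    """Load the CSV, transparently unwrapping a single-member ZIP archive."""
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            members = [m for m in zf.namelist() if not m.endswith("/")]
            if len(members) != 1:
                raise FormatError(
                    f"ZIP archive must contain exactly one CSV, found {len(members)} members"
                )
            with zf.open(members[0]) as fh:
                return pd.read_csv(_stdio.TextIOWrapper(fh, encoding="utf-8"))
    return pd.read_csv(path)


def read_repertoire(path, label_column: str = "label", index_col="auto") -> RepertoireMatrix:
    """Read and validate a labeled clonotype count table.

    Parameters
    ----------
    path : path-like
        CSV file, or ZIP archive containing exactly one CSV.
    label_column : str
        Name of the column holding the per-sample label.  Required to exist.
    index_col : "auto" | bool
        Whether the first column holds sample identifiers.  ``"auto"``
        (default) treats it as an index when its header is empty/pandas'
        ``Unnamed: 0`` placeholder or its values are non-numeric strings;
        otherwise sample ids ``s0, s1, ...`` are generated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv_payload(path)

    first = df.columns[0]
    use_index = index_col
    if index_col == "auto":
        use_index = first == "" or str(first).startswith("Unnamed:") or (
            df[first].dtype == object
        )
    if use_index:
        df = df.set_index(first)
        df.index = df.index.astype(str)
        df.index.name = None
        sample_ids = [str(s) for s in df.index]
    else:
        sample_ids = [f"s{i}" for i in range(len(df))]
        df.index = sample_ids

    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; available columns: "
            f"{list(df.columns)}"
        )
    labels = df[label_column].astype(str)
    counts_df = df.drop(columns=[label_column])

    # undo pandas' mangling of duplicate header names ("X", "X.1", ...)
    demangled = {}
    for col in counts_df.columns:
        base, dot, suffix = str(col).rpartition(".")
        if dot and suffix.isdigit() and base in counts_df.columns:
            demangled[col] = base
    if demangled:
        counts_df = counts_df.rename(columns=demangled)

    if counts_df.columns.duplicated().any():
        dups = sorted(set(counts_df.columns[counts_df.columns.duplicated()]))
        warnings.warn(
            f"duplicate clonotype columns merged by summation: {dups}", stacklevel=2
        )
        counts_df = counts_df.T.groupby(level=0, sort=False).sum().T

    for col in counts_df.columns:
        if not np.issubdtype(counts_df[col].dtype, np.number):
            raise ValidationError(f"non-numeric counts in column {col!r}")
    counts = counts_df.to_numpy()
    _validate_counts(counts)

    return RepertoireMatrix(
        sample_ids=sample_ids,
        clonotypes=[str(c) for c in counts_df.columns],
        counts=counts.astype(np.int64),
        labels=labels,
        label_column_name=label_column,
    )


def write_table(table, path) -> None:
    """Write any tabular artifact (FeatureTable, ranking, report, DataFrame) as CSV.

    Values round-trip at full double precision; integer columns stay integers.
    """
    if hasattr(table, "to_frame"):
        df = table.to_frame()
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        raise TypeError(f"cannot write object of type {type(table).__name__}")
    vals = df.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    if vals.size and not np.isfinite(vals).all():
        raise ValidationError("refusing to write non-finite values")
    df.to_csv(path, float_format="%.17g")


def read_table(path, label_column=None):
    """Read back a CSV artifact; with ``label_column`` returns a FeatureTable."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if label_column is None:
        return df
    return FeatureTable.from_frame(df, label_column=label_column)


def save_model(model, path) -> None:
    """Serialize a trained classifier into a self-describing versioned container."""
    payload = {
        "container": "tcrlearn-model",
        "format_version": MODEL_FORMAT_VERSION,
        "library_version": __version__,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path):
    """Load a model container written by :func:`save_model`.

    Raises :class:`ModelFormatError` on corrupted files or incompatible
    schema versions rather than returning silent garbage.
    """
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, UnicodeDecodeError) as e:
        raise ModelFormatError(f"cannot read model container {path}: {e}") from e
    if not isinstance(payload, dict) or payload.get("container") != "tcrlearn-model":
        raise ModelFormatError(f"{path} is not a tcrlearn model container")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model container version {payload.get('format_version')} is incompatible "
            f"with library container version {MODEL_FORMAT_VERSION}"
        )
    return payload["model"]
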