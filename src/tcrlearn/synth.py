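"""Synthetic labeled repertoire cohorts with controllable evenness contrast.

Each sample's clone proportions are drawn from a symmetric Dirichlet with a
group-specific concentration ``alpha`` (small alpha -> clonal/uneven, large
alpha -> even), or alternatively from a power law; counts are then drawn
multinomially with ``n_reads`` reads, so every sample's counts sum to
``n_reads`` exactly.  Clonotype columns are CDR3-like strings
(``CASS`` + random core + ``F``) shared by all samples of a cohort.
Diversity indices therefore separate the two groups with a strength set by
the alpha contrast, emulating case/control repertoire studies where groups
differ in clone-abundance evenness.

An optional ``cluster`` mode derives part of the sequence pool as 1-2-edit
variants of seed sequences, so per-sample Levenshtein-threshold graphs have
nontrivial edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import RepertoireMatrix

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CohortSpec:
    """Parameters of one two-group synthetic cohort.

    ``abundance_law`` is ``"dirichlet"`` (``alpha`` = per-group symmetric
    concentration) or ``"powerlaw"`` (``alpha`` = per-group exponent of
    ``p_i ~ i^-alpha``; larger exponent = more clonal).
    """

    n_per_group: tuple = (8, 8)
    group_labels: tuple = ("A", "B")
    n_clonotypes: int = 200
    n_reads: int = 5000
    alpha: tuple = (100.0, 0.1)
    abundance_law: str = "dirichlet"
    length_range: tuple = (8, 18)
    cluster_mode: bool = False
    seed: int = 0
    label_column: str = "label"

    def __post_init__(self):
        if self.abundance_law not in ("dirichlet", "powerlaw"):
            raise ConfigurationError(f"unknown abundance law {self.abundance_law!r}")
        if any(a <= 0 for a in self.alpha):
            raise ConfigurationError("alpha must be positive")
        if not (self.n_reads >= self.n_clonotypes >= 1):
            raise ConfigurationError("need n_reads >= n_clonotypes >= 1")
        if len(self.n_per_group) != 2 or len(self.group_labels) != 2:
            raise ConfigurationError("exactly two groups are required")
        lo, hi = self.length_range
        if not (6 <= lo <= hi):
            raise ConfigurationError("CDR3 lengths must be >= 6 (CASS...F frame)")


def _random_cdr3(rng: np.random.Generator, length_range) -> str:
    lo, hi = length_range
    n = int(rng.integers(lo, hi + 1))
    core = "".join(rng.choice(list(AA), size=n - 5))
    return f"CASS{core}F"


def _mutate(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    s = list(seq)
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"]) if len(s) > 7 else "sub"
        i = int(rng.integers(4, len(s) - 1))  # keep the CASS...F frame
        if op == "sub":
            s[i] = rng.choice(list(AA))
        elif op == "ins":
            s.insert(i, rng.choice(list(AA)))
        else:
            del s[i]
    return "".join(s)


def _sequence_pool(rng: np.random.Generator, spec: CohortSpec) -> list:
    pool: dict[str, None] = {}
    if spec.cluster_mode:
        # seed sequences plus 1-2-edit variants -> Levenshtein-close pairs
        while len(pool) < spec.n_clonotypes:
            seed_seq = _random_cdr3(rng, spec.length_range)
            pool.setdefault(seed_seq)
            for _ in range(int(rng.integers(2, 6))):
                if len(pool) >= spec.n_clonotypes:
                    break
                pool.setdefault(_mutate(rng, seed_seq, int(rng.integers(1, 3))))
    else:
        while len(pool) < spec.n_clonotypes:
            pool.setdefault(_random_cdr3(rng, spec.length_range))
    return list(pool)[: spec.n_clonotypes]


def _proportions(rng: np.random.Generator, spec: CohortSpec, group: int) -> np.ndarray:
    s = spec.n_clonotypes
    a = spec.alpha[group]
    if spec.abundance_law == "dirichlet":
        return rng.dirichlet(np.full(s, a))
    ranks = np.arange(1, s + 1, dtype=float)
    p = rng.permutation(ranks ** -a)
    return p / p.sum()


def generate_cohort(spec: CohortSpec) -> RepertoireMatrix:
    """Draw one labeled cohort; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    clonotypes = _sequence_pool(rng, spec)
    rows, sample_ids, labels = [], [], []
    for g, (n, lab) in enumerate(zip(spec.n_per_group, spec.group_labels)):
        for j in range(n):
            p = _proportions(rng, spec, g)
            rows.append(rng.multinomial(spec.n_reads, p))
            sample_ids.append(f"{lab}_{j}")
            labels.append(lab)
    return RepertoireMatrix(
        sample_ids=sample_ids,
        clonotypes=clonotypes,
        counts=np.asarray(rows, dtype=np.int64),
        labels=pd.Series(labels, index=sample_ids),
        label_column_name=spec.label_column,
    )


def generate_paired_cohorts(spec: CohortSpec, spec2: CohortSpec | None = None):
    """Two independent cohorts with the same group-level effect direction,
    for the train-on-A / validate-on-B protocol.

    ``spec2`` defaults to ``spec`` with an independent derived seed; it must
    share ``spec``'s group labels.
    """
    if spec2 is None:
        spec2 = replace(spec, seed=(spec.seed + 1_000_003) % (2**31 - 1))
    if tuple(spec2.group_labels) != tuple(spec.group_labels):
        raise ConfigurationError(
            f"paired cohorts must share group labels; got {spec.group_labels} "
            f"vs {spec2.group_labels}"
        )
    if spec2.seed == spec.seed:
        spec2 = replace(spec2, seed=(spec.seed + 1_000_003) % (2**31 - 1))
    return generate_cohort(spec), generate_cohort(spec2)
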