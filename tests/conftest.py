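import numpy as np
import pandas as pd
import pytest

from tcrlearn import CohortSpec, FeatureTable, RepertoireMatrix, generate_cohort


@pytest.fixture
def tiny_matrix():
    """3 samples x 4 clonotypes with a binary label."""
    return RepertoireMatrix(
        sample_ids=["s1", "s2", "s3"],
        clonotypes=["CASSF", "CASSG", "CASRF", "WWWWWWWW"],
        counts=np.array([[3, 2, 1, 0], [10, 0, 0, 0], [1, 1, 1, 1]]),
        labels=pd.Series(["case", "ctrl", "case"], index=["s1", "s2", "s3"]),
        label_column_name="label",
    )


@pytest.fixture
def small_cohort():
    """4 + 4 samples with a strong evenness contrast; fast to generate."""
    return generate_cohort(CohortSpec(
        n_per_group=(4, 4), n_clonotypes=50, n_reads=500,
        alpha=(100.0, 0.1), seed=7,
    ))


def make_feature_table(n=12, features=None, seed=0, labels=None):
    """Random feature table helper with an even binary label by default."""
    rng = np.random.default_rng(seed)
    features = features or ["f1", "f2", "f3"]
    data = pd.DataFrame(rng.normal(size=(n, len(features))),
                        index=[f"s{i}" for i in range(n)], columns=features)
    if labels is None:
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return FeatureTable(data=data,
                        labels=pd.Series(labels, index=data.index))
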