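import numpy as np
import pandas as pd
import pytest

from sctri import AnnotationTable, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_blob_matrix(rng):
    """Two well-separated spherical clusters, 60 cells x 40 features."""
    n_per, n_feat = 30, 40
    a = rng.normal(0.0, 1.0, size=(n_per, n_feat))
    b = rng.normal(0.0, 1.0, size=(n_per, n_feat))
    b[:, :10] += 8.0
    a[:, 10:20] += 8.0
    values = np.vstack([a, b])
    values -= values.min()  # keep the >0 binarization meaningful
    X = FeatureMatrix(
        values=values,
        cell_ids=[f"cell{i}" for i in range(2 * n_per)],
        feature_ids=[f"RNA:g{j}" for j in range(n_feat)],
        feature_modality=["RNA"] * n_feat,
    )
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return X, labels


@pytest.fixture
def three_group_matrix(rng):
    """Three groups with disjoint strong marker blocks (90 cells x 60 features)."""
    n_per, n_feat = 30, 60
    values = rng.normal(0.0, 0.5, size=(3 * n_per, n_feat)) ** 2
    for g in range(3):
        rows = slice(g * n_per, (g + 1) * n_per)
        cols = slice(g * 15, g * 15 + 15)
        values[rows, cols] += 5.0
    X = FeatureMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(3 * n_per)],
        feature_ids=[f"RNA:g{j}" for j in range(n_feat)],
        feature_modality=["RNA"] * n_feat,
    )
    labels = np.repeat(["g0", "g1", "g2"], n_per)
    return X, labels


@pytest.fixture
def annotation_table():
    labels = pd.DataFrame(
        {
            "fine": ["a", "a", "b", "b", "c", "c"],
            "coarse": ["ab", "ab", "ab", "ab", "c", "c"],
        },
        index=[f"cell{i}" for i in range(6)],
    )
    return AnnotationTable(labels=labels)
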