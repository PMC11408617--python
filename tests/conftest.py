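import numpy as np
import pandas as pd
import pytest

from spatialniche import CellTable, TypeVocabulary


@pytest.fixture
def abc_vocab():
    return TypeVocabulary.from_names(["A", "B", "C"])


@pytest.fixture
def small_table(abc_vocab):
    """3 collinear cells plus one off-axis, single sample."""
    frame = pd.DataFrame({
        "sample_id": ["s1"] * 4,
        "cell_id": ["c0", "c1", "c2", "c3"],
        "x_px": [0.0, 1.0, 2.0, 3.0],
        "y_px": [0.0, 0.0, 0.0, 0.0],
        "cell_type": ["A", "A", "B", "C"],
    })
    return CellTable(frame, abc_vocab)


def make_random_table(n, n_types=3, seed=0, n_samples=1, canvas=1000.0):
    rng = np.random.default_rng(seed)
    vocab = TypeVocabulary.from_names([f"T{i}" for i in range(n_types)])
    frame = pd.DataFrame({
        "sample_id": [f"s{i % n_samples}" for i in range(n)],
        "cell_id": [f"c{i}" for i in range(n)],
        "x_px": rng.uniform(0, canvas, n),
        "y_px": rng.uniform(0, canvas, n),
        "cell_type": [vocab.names[t] for t in rng.integers(0, n_types, n)],
    })
    return CellTable(frame, vocab), vocab


def brute_force_knn(coords, k):
    """Quadratic all-pairs oracle: (distance, index) ordering via stable sort."""
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return order, dist
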