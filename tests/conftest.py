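import numpy as np
import pytest

from swiss import ClassAssignment, ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Four samples at the corners of a 4x2 rectangle, two features.

    Hand-computed: overall mean (2, 1), SST = 20; class means (0, 1) and
    (4, 1), WISS = 4, SWISS = 0.2.
    """
    values = np.array([[0.0, 0.0, 4.0, 4.0], [0.0, 2.0, 0.0, 2.0]])
    return ExpressionMatrix(values, ("g1", "g2"), ("s1", "s2", "s3", "s4"))


@pytest.fixture
def toy_labels() -> ClassAssignment:
    return ClassAssignment.from_pairs([("s1", "a"), ("s2", "a"), ("s3", "b"), ("s4", "b")])


def random_instance(rng: np.random.Generator, d: int = 5, n: int = 6, k: int = 2):
    """A random complete matrix with a random labeling (every class used)."""
    values = rng.normal(size=(d, n))
    ids = tuple(f"s{j}" for j in range(n))
    X = ExpressionMatrix(values, tuple(f"g{i}" for i in range(d)), ids)
    while True:
        labels = rng.integers(0, k, size=n)
        if len(set(labels)) == k:
            break
    C = ClassAssignment.from_pairs((ids[j], f"c{labels[j]}") for j in range(n))
    return X, C
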