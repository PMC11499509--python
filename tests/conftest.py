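import numpy as np
import pytest

from mltlsmote import MultiLabelDataset

# The six-label example records used throughout the worked examples:
# rows 001011, 001110, 011100, 111001, 111110.
TABLE_ROWS = np.array(
    [
        [0, 0, 1, 0, 1, 1],
        [0, 0, 1, 1, 1, 0],
        [0, 1, 1, 1, 0, 0],
        [1, 1, 1, 0, 0, 1],
        [1, 1, 1, 1, 1, 0],
    ],
    dtype=np.int8,
)


@pytest.fixture
def example_records() -> MultiLabelDataset:
    """Five records with known Card 3.6, Dens 0.6, DC 5 and IRLbl
    (2.5, 5/3, 1, 5/3, 5/3, 2.5)."""
    rng = np.random.default_rng(0)
    return MultiLabelDataset(
        features=rng.normal(size=(5, 3)),
        labels=TABLE_ROWS,
        label_names=tuple(f"label_{j}" for j in range(1, 7)),
        feature_names=("x1", "x2", "x3"),
    )


def random_mld(rng: np.random.Generator, m: int, q: int, d: int = 3,
               ensure_positive: bool = True) -> MultiLabelDataset:
    """A random dense MLD; optionally guarantee >=1 positive per label."""
    labels = (rng.random((m, q)) < rng.uniform(0.2, 0.8, size=q)).astype(
        np.int8)
    if ensure_positive:
        for j in range(q):
            if labels[:, j].sum() == 0:
                labels[rng.integers(m), j] = 1
    return MultiLabelDataset(
        features=rng.normal(size=(m, d)),
        labels=labels,
        label_names=tuple(f"L{j}" for j in range(q)),
        feature_names=tuple(f"x{j}" for j in range(d)),
    )
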