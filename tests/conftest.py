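import numpy as np
import pytest

from apmsnet.io import Purification, PurificationDataset


def random_dataset(rng, n_purifications=30, n_proteins=20, max_preys=6):
    """A random qualitative AP-MS dataset for oracle comparisons."""
    proteins = [f"Y{i:03d}" for i in range(n_proteins)]
    purifications = []
    for t in range(n_purifications):
        bait = proteins[int(rng.integers(n_proteins))]
        n_prey = int(rng.integers(0, min(max_preys, n_proteins) + 1))
        preys = frozenset(
            proteins[i] for i in rng.choice(n_proteins, size=n_prey, replace=False)
        ) - {bait}
        purifications.append(Purification(f"e{t}", bait, preys))
    return PurificationDataset(purifications)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """The two-purification hand-countable example used across modules."""
    return PurificationDataset(
        [
            Purification("p1", "A", frozenset({"B", "C"})),
            Purification("p2", "B", frozenset({"A"})),
        ]
    )
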