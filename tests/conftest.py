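import numpy as np
import pytest

from dropgate import DropletTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_blobs(rng, centres, n_per=50, sd=200.0, labels=None):
    """Four Gaussian blobs around the given centres as a DropletTable."""
    centres = np.asarray(centres, dtype=float)
    pts = np.concatenate(
        [c + rng.normal(0, sd, size=(n_per, 2)) for c in centres]
    )
    lab = None
    if labels is not None:
        lab = np.repeat(labels, n_per)
    return DropletTable(pts[:, 0], pts[:, 1], lab)


SQUARE_CENTRES = np.array(
    [[1000.0, 1000.0], [1000.0, 8000.0], [9000.0, 1000.0], [9000.0, 8000.0]]
)
SQUARE_LABELS = ("NN", "NP", "PN", "PP")


@pytest.fixture
def blob_table(rng):
    return make_blobs(rng, SQUARE_CENTRES, n_per=50, sd=200.0, labels=SQUARE_LABELS)
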