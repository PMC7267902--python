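import numpy as np
import pytest

from bundlerepro import ReferenceGrid, Selection, Tractogram, make_phantom


@pytest.fixture(scope="session")
def grid32():
    return ReferenceGrid.isotropic((32, 32, 32))


@pytest.fixture(scope="session")
def phantom():
    """Small deterministic phantom shared across tests (read-only)."""
    parent, truth = make_phantom(n_core=80, n_distractor=40, seed=7)
    return parent, truth


@pytest.fixture(scope="session")
def tiny_parent(grid32):
    """Hand-built 6-streamline parent with two bit-identical streamlines
    (indices 2 and 3), for duplicate-matching and measure tests."""
    rng = np.random.default_rng(11)
    base = [rng.uniform(5, 25, size=(5, 3)) for _ in range(5)]
    base.insert(3, base[2].copy())  # exact duplicate of index 2
    return Tractogram([np.asarray(s, float) for s in base], grid32, "tiny")


def selection(parent, idx):
    return Selection(parent.id, np.asarray(idx, dtype=np.int64))
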