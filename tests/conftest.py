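import numpy as np
import pytest

from gmdecon import CellAnnotation, CountMatrix, FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small but separable synthetic dataset shared by fast tests."""
    spec = FixtureSpec(n_types=4, n_genes=80, markers_per_type=6, n_ref_cells=200,
                       grid_shape=(8, 8), n_domains=2, seed=7)
    return make_fixture(spec)


@pytest.fixture
def small_reference():
    """A hand-sized annotated reference: 9 cells, 3 types, 5 genes."""
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 20, size=(9, 5))
    ids = [f"c{i}" for i in range(9)]
    genes = [f"g{j}" for j in range(5)]
    types = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
    return CountMatrix(counts, ids, genes), CellAnnotation(ids, types)
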