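import numpy as np
import pytest

import contactbench as cb


@pytest.fixture(scope="session")
def default_protein() -> cb.SyntheticProtein:
    """The default synthetic protein family (study conditions)."""
    return cb.generate(cb.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_protein() -> cb.SyntheticProtein:
    """A quick 30-residue fixture for geometry/confusion tests."""
    return cb.generate(cb.GeneratorConfig(n_residues=30, n_sequences=40, seed=7))


@pytest.fixture(scope="session")
def benchmark():
    """The bundled 45-row published benchmark grid (1a4v)."""
    return cb.load_benchmark_1a4v()


@pytest.fixture()
def toy_coords() -> cb.CoordinateSet:
    """Three collinear CA positions 4 Å apart."""
    pts = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
    return cb.CoordinateSet(pts, (1, 2, 3))


def make_alignment(*seqs: str) -> cb.Alignment:
    return cb.Alignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))


def column_alignment(column: str) -> cb.Alignment:
    """Alignment whose single column is ``column`` read downwards."""
    return cb.Alignment(tuple((f"s{i}", c) for i, c in enumerate(column)))
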