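import numpy as np
import pytest

from hingeaxis import fixtures
from hingeaxis.structure_model import infer_covalent_bonds, read_pdb


@pytest.fixture
def hinge_fixture():
    """Two rigid blocks joined by one hinge on a known off-origin line."""
    return fixtures.make_hinge_fixture(
        block_size=6, axis_point=(1.0, 2.0, 3.0), axis_direction=(0.3, 0.4, 0.5), seed=2
    )


@pytest.fixture
def toy_protein(tmp_path):
    """Toy hinge structure written to disk and re-read through the parser."""
    toy = fixtures.make_toy_protein(seed=0)
    path = tmp_path / "toy.pdb"
    path.write_text(toy.pdb_text)
    molecule = read_pdb(path)
    molecule.covalent_bonds = infer_covalent_bonds(molecule)
    return toy, molecule, path


def gaussian_kernel(a: np.ndarray) -> np.ndarray:
    """Null-space basis by plain Gaussian elimination (independent oracle)."""
    a = np.array(a, dtype=float)
    m, n = a.shape
    pivots = []
    row = 0
    for col in range(n):
        piv = None
        for r in range(row, m):
            if abs(a[r, col]) > 1e-10:
                piv = r
                break
        if piv is None:
            continue
        a[[row, piv]] = a[[piv, row]]
        a[row] = a[row] / a[row, col]
        for r in range(m):
            if r != row and abs(a[r, col]) > 1e-14:
                a[r] -= a[r, col] * a[row]
        pivots.append(col)
        row += 1
        if row == m:
            break
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        v = np.zeros(n)
        v[fc] = 1.0
        for r, pc in enumerate(pivots):
            v[pc] = -a[r, fc]
        basis.append(v)
    return np.array(basis) if basis else np.zeros((0, n))
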