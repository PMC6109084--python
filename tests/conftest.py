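"""Shared fixtures: small synthetic structures built programmatically."""

import numpy as np
import pytest

from poregate.core_io import Structure

GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
END
"""


@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return str(path)


def random_structure(n_atoms: int, seed: int = 0, spread: float = 10.0) -> Structure:
    """A random cloud of C/N/O/S atoms with consecutive residue numbering."""
    rng = np.random.default_rng(seed)
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms)
    masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    return Structure(
        ids=np.arange(1, n_atoms + 1),
        elements=elements,
        names=[f"{e}{i}" for i, e in enumerate(elements)],
        resnames=["UNK"] * n_atoms,
        resids=1 + np.arange(n_atoms) // 4,
        chains=["A"] * n_atoms,
        coords=rng.uniform(-spread, spread, size=(n_atoms, 3)),
        masses=np.array([masses[e] for e in elements]),
    )


def water_structure(coords: np.ndarray, start_id: int = 1) -> Structure:
    """One oxygen atom per water at the given positions (resname HOH)."""
    n = len(coords)
    return Structure(
        ids=start_id + np.arange(n),
        elements=["O"] * n,
        names=["O"] * n,
        resnames=["HOH"] * n,
        resids=np.arange(1, n + 1),
        chains=["W"] * n,
        coords=np.asarray(coords, dtype=float),
        masses=np.full(n, 15.999),
    )


def random_rigid_transform(seed: int):
    """A random rotation matrix and translation vector."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20, 20, size=3)
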