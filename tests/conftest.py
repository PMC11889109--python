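"""Shared fixtures: all test structures are generated programmatically."""

import numpy as np
import pytest

from baseflip import DuplexSpec, apply_base_flip, build_duplex, build_mock_complex

SEQUENCE_17 = "CAGGATGTATATATCTG"


@pytest.fixture(scope="session")
def duplex():
    """Idealized 17-mer duplex with uracil at position 12, with hydrogens."""
    return build_duplex(DuplexSpec(SEQUENCE_17, (12,), with_hydrogens=True))


@pytest.fixture(scope="session")
def duplex_noh():
    return build_duplex(DuplexSpec(SEQUENCE_17, (12,)))


@pytest.fixture(scope="session")
def flipped_duplex(duplex):
    return apply_base_flip(duplex, ("A", 12), 175.0, "major")


@pytest.fixture(scope="session")
def mock_complex(flipped_duplex):
    return build_mock_complex(flipped_duplex, pocket_atoms=40, seed=11)


TOY_PDB = """\
HEADER    TOY
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.660   6.883  -4.307  1.00  0.00           C
END
"""

PEPTIDE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      6  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture()
def peptide_pdb(tmp_path):
    p = tmp_path / "peptide.pdb"
    p.write_text(PEPTIDE_PDB)
    return p


def random_rigid_transform(rng):
    """Uniform-ish random proper rotation + translation (test helper)."""
    from baseflip import RigidTransform
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return RigidTransform(q, rng.normal(scale=20.0, size=3))
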