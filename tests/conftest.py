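"""Shared fixtures: inline PDB text and toy coordinate structures."""

import numpy as np
import pytest

from chidist.synthetic import build_toy_structure

# Two chains: ALA + SER (with altloc'd N) in A, GLY in B; one hydrogen and
# one water that the reader must drop.
PDB_FIXTURE = """\
HEADER    TEST STRUCTURE
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.937  1.00  0.00           C
ATOM      4  O   ALA A   1      13.402   7.536  -5.871  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.208   4.687  -4.853  1.00  0.00           C
ATOM      6  H   ALA A   1      10.500   5.500  -7.000  1.00  0.00           H
ATOM      7  N  ASER A   2      10.000   0.000   0.000  0.60  0.00           N
ATOM      8  N  BSER A   2      10.500   0.000   0.000  0.40  0.00           N
ATOM      9  CA  SER A   2      11.000   1.000   0.000  1.00  0.00           C
ATOM     10  CB  SER A   2      12.000   1.500   0.000  1.00  0.00           C
ATOM     11  OG  SER A   2      12.500   2.500   0.500  1.00  0.00           O
ATOM     12  C   SER A   2      11.200   2.000   1.000  1.00  0.00           C
ATOM     13  O   SER A   2      11.300   3.000   1.500  1.00  0.00           O
ATOM     14  N   GLY B   1       0.000   0.000   0.000  1.00  0.00           N
ATOM     15  CA  GLY B   1       1.458   0.000   0.000  1.00  0.00           C
HETATM   16  O   HOH A 100       5.000   5.000   5.000  1.00  0.00           O
TER
END
"""

MINIMAL_ALA = "\n".join(PDB_FIXTURE.splitlines()[1:6]) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def toy_complex():
    """Two-chain toy complex: chain A residues near chain B's first residue.

    The A1/B1 pair sits ~6 A apart (side chains occlude each other, losing
    SASA on extraction), while A2/A3/B2 are far from everything else.
    """
    return build_toy_structure([
        ("A", 1, "SER", (62.0,), (0.0, 0.0, 0.0)),
        ("A", 2, "ASP", (-60.0, 150.0), (40.0, 0.0, 0.0)),
        ("A", 3, "MET", (-60.0, 180.0, 75.0), (80.0, 0.0, 0.0)),
        ("B", 1, "LEU", (-65.0, 170.0), (3.0, 4.0, 1.0)),
        ("B", 2, "LYS", (-60.0, 180.0, 60.0, 180.0), (40.0, 40.0, 0.0)),
    ])
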