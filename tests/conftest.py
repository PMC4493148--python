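"""Shared fixtures: crafted structure files and reusable synthetic cases."""
from __future__ import annotations

import textwrap

import numpy as np
import pytest

import endock
from endock import FixtureSpec, fixtures

# -- crafted file contents ---------------------------------------------------

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.100  -4.900  1.00  0.00           C
ATOM      4  O   ALA A   1      13.500   7.300  -5.800  1.00  0.00           O
ATOM      5  N   SER A   2      12.700   7.800  -3.760  1.00  0.00           N
ATOM      6  CA  SER A   2      13.600   8.900  -3.400  1.00  0.00           C
ATOM      7  OG  SER A   2      13.000  10.100  -3.900  1.00  0.00           O
ATOM      8  N   LEU A   3      14.100   8.800  -1.990  1.00  0.00           N
ATOM      9  CA  LEU A   3      15.000   9.800  -1.400  1.00  0.00           C
ATOM     10  CD1 LEU A   3      16.300   9.200  -0.850  1.00  0.00           C
HETATM   11  O   HOH A 101       2.000   2.000   2.000  1.00  0.00           O
HETATM   12  O   HOH A 102       3.000   3.000   3.000  1.00  0.00           O
HETATM   13  C1  LIG A 201      12.000   8.000  -4.000  1.00  0.00           C
HETATM   14  C2  LIG A 201      12.800   8.600  -3.200  1.00  0.00           C
END
"""

ZINC_PDB = THREE_RES_PDB.replace(
    "END\n",
    "HETATM   15 ZN    ZN A 301       9.000   9.000   9.000  1.00  0.00"
    "          ZN\nEND\n",
)

MG_CA_PDB = THREE_RES_PDB.replace(
    "END\n",
    "HETATM   15 MG    MG A 301       9.000   9.000   9.000  1.00  0.00"
    "          MG\n"
    "HETATM   16 CA    CA A 302       8.000   8.000   8.000  1.00  0.00"
    "          CA\nEND\n",
)

RIGID_LIGAND_PDBQT = """\
ROOT
ATOM      1  C1  UNL A   1       0.000   0.000   0.000  1.00  0.00     0.000 C
ATOM      2  C2  UNL A   1       1.500   0.000   0.000  1.00  0.00     0.000 C
ATOM      3  O3  UNL A   1       2.100   1.200   0.000  1.00  0.00     0.000 OA
ENDROOT
TORSDOF 0
"""

NESTED_BRANCH_PDBQT = """\
ROOT
ATOM      1  C1  UNL A   1       0.000   0.000   0.000  1.00  0.00     0.000 C
ATOM      2  C2  UNL A   1       1.500   0.000   0.000  1.00  0.00     0.000 C
ENDROOT
BRANCH   2   3
ATOM      3  C3  UNL A   1       2.100   1.400   0.000  1.00  0.00     0.000 C
BRANCH   3   4
ATOM      4  C4  UNL A   1       3.600   1.400   0.000  1.00  0.00     0.000 C
ATOM      5  O5  UNL A   1       4.200   2.600   0.000  1.00  0.00     0.000 OA
ENDBRANCH   3   4
ENDBRANCH   2   3
TORSDOF 2
"""

BUTANE_MOL2 = """\
@<TRIPOS>MOLECULE
butane
 4 3 1
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1         0.0000    0.0000    0.0000 C.3     1  BUT1
      2 C2         1.5300    0.0000    0.0000 C.3     1  BUT1
      3 C3         2.0400    1.4400    0.0000 C.3     1  BUT1
      4 C4         3.5700    1.4400    0.0000 C.3     1  BUT1
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
     3    3    4 1
"""


@pytest.fixture()
def three_res_pdb(tmp_path):
    p = tmp_path / "threeres.pdb"
    p.write_text(THREE_RES_PDB)
    return p


@pytest.fixture()
def zinc_pdb(tmp_path):
    p = tmp_path / "zinc.pdb"
    p.write_text(ZINC_PDB)
    return p


@pytest.fixture()
def mg_ca_pdb(tmp_path):
    p = tmp_path / "mgca.pdb"
    p.write_text(MG_CA_PDB)
    return p


@pytest.fixture()
def rigid_ligand_pdbqt(tmp_path):
    p = tmp_path / "rigid.pdbqt"
    p.write_text(RIGID_LIGAND_PDBQT)
    return p


@pytest.fixture()
def nested_branch_pdbqt(tmp_path):
    p = tmp_path / "nested.pdbqt"
    p.write_text(NESTED_BRANCH_PDBQT)
    return p


@pytest.fixture()
def butane_mol2(tmp_path):
    p = tmp_path / "butane.mol2"
    p.write_text(BUTANE_MOL2)
    return p


# -- synthetic cases (session-scoped: construction is moderately expensive) --


@pytest.fixture(scope="session")
def small_ligand():
    return fixtures.make_ligand(FixtureSpec(seed=11, heavy_atoms=8, torsions=2))


@pytest.fixture(scope="session")
def rigid_case():
    return fixtures.make_redock_case(
        FixtureSpec(seed=21, heavy_atoms=8, torsions=0)
    )


@pytest.fixture(scope="session")
def flexible_case():
    return fixtures.make_redock_case(
        FixtureSpec(seed=22, heavy_atoms=10, torsions=2)
    )
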