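import numpy as np
import pytest

from ppisasa.structio import Atom, LigandPose, ReceptorStructure, _pose_from_rdkit


def make_atom(serial, x, y, z, element="C", radius=1.70, **kw):
    return Atom(
        serial=serial,
        element=element,
        coords=np.array([x, y, z], dtype=float),
        vdw_radius=radius,
        **kw,
    )


def pose_from_smiles(smiles: str, compound_id: str = "lig", add_hs: bool = True) -> LigandPose:
    """Build a 3D ligand pose from SMILES via RDKit embedding."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if add_hs:
        mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=0xF00D)
    mol.SetProp("_Name", compound_id)
    return _pose_from_rdkit(mol, compound_id, f"{compound_id}_0", 0.0)


@pytest.fixture
def simple_receptor():
    atoms = [
        make_atom(1, 0.0, 0.0, 0.0, "N", 1.55, name="N", residue_name="GLY", residue_id=1, chain="A"),
        make_atom(2, 1.5, 0.0, 0.0, name="CA", residue_name="GLY", residue_id=1, chain="A"),
        make_atom(3, 3.0, 0.0, 0.0, name="C", residue_name="GLY", residue_id=1, chain="A"),
        make_atom(4, 3.6, 1.1, 0.0, "O", 1.52, name="O", residue_name="GLY", residue_id=1, chain="A"),
    ]
    return ReceptorStructure(atoms=atoms, source_id="test")


PDB_THREE_ATOMS = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       4.000   2.000   3.000  1.00  0.00           C
END
"""

PDB_WITH_WATER = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
HETATM    3  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
ATOM      3  CB  ALA A   1       3.000   0.000   0.000  1.00  0.00           C
END
"""

SDF_TWO_RECORDS = """\
mol_a
  test

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
>  <score>
1.5

$$$$
mol_b
  test

  1  0  0  0  0  0  0  0  0  0999 V2000
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
>  <score>
2.5

$$$$
"""

MOL2_ETHANOL = """\
@<TRIPOS>MOLECULE
ethanol
 3 2 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 C1          0.0000    0.0000    0.0000 C.3     1  ETH         0.0000
      2 C2          1.5200    0.0000    0.0000 C.3     1  ETH         0.0000
      3 O1          2.0800    1.3000    0.0000 O.3     1  ETH         0.0000
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
"""
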