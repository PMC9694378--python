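"""Structure input/output: receptors, ligand poses, binding sites, complexes.

Receptor structures are read from PDB files (via Biopython), ligand poses
from SDF or MOL2 files (via RDKit).  Atoms are plain records carrying
coordinates, element, van der Waals radius and bookkeeping fields; every
downstream surface-area quantity is computed over these records.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Bondi (1964) van der Waals radii, Angstrom.  Configurable: pass your own
# table to assign_vdw_radii.  Unknown elements fall back to DEFAULT_VDW_RADIUS.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.80

# Residue names dropped by default (crystallographic solvent and common ions).
DEFAULT_DROP_RESIDUES = frozenset(
    {"HOH", "WAT", "DOD", "NA", "K", "CL", "MG", "ZN", "CA", "MN", "FE", "SO4", "PO4"}
)


class EmptyStructureError(ValueError):
    """Raised when a parsed structure retains zero atoms."""


class EmptyBindingSiteError(ValueError):
    """Raised when no receptor residue lies within the contact cutoff."""


@dataclass
class Atom:
    serial: int
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = 0.0
    name: str = ""
    residue_name: str = ""
    residue_id: int = 0
    chain: str = ""
    is_ligand: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")


@dataclass
class ReceptorStructure:
    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("receptor structure has no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in receptor structure")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class LigandPose:
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    compound_id: str = ""
    pose_id: str = ""
    native_score: float = math.nan
    rdkit_mol: object = None  # retained for SMARTS typing; not required

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError("ligand pose has no atoms")
        if not self.compound_id:
            raise ValueError("ligand pose requires a non-empty compound_id")
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class PoseComplex:
    receptor_subset: ReceptorStructure
    ligand: LigandPose
    cutoff_used: float = math.nan

    def all_atoms(self) -> list[Atom]:
        return list(self.receptor_subset.atoms) + list(self.ligand.atoms)


def read_receptor(
    path: str | Path,
    source_id: str | None = None,
    drop_residues: frozenset[str] = DEFAULT_DROP_RESIDUES,
) -> ReceptorStructure:
    """Read a receptor from a PDB file.

    Waters/ions (``drop_residues``) are removed; for alternate locations only
    the highest-occupancy conformer is kept (Biopython's default selection);
    hydrogens are retained if present, never added.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise IOError(f"receptor file not found: {path}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(source_id or path.stem, str(path))
    except Exception as exc:  # pragma: no cover - Biopython raises varied types
        raise IOError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms: list[Atom] = []
    model = next(structure.get_models())  # first model only
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in drop_residues:
                continue
            het, resseq, _icode = residue.get_id()
            for atom in residue.get_atoms():
                # DisorderedAtom iteration yields the selected (highest
                # occupancy) altloc only.
                element = (atom.element or "").strip().upper() or _guess_element(atom.get_name())
                atoms.append(
                    Atom(
                        serial=atom.get_serial_number(),
                        element=element,
                        coords=np.array(atom.get_coord(), dtype=float),
                        name=atom.get_name(),
                        residue_name=resname,
                        residue_id=int(resseq),
                        chain=chain.get_id(),
                        is_ligand=False,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"no atoms retained from {path}")
    return ReceptorStructure(atoms=atoms, source_id=source_id or path.stem)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "SE"):
        return stripped[:2].upper()
    return stripped[:1].upper() if stripped else "C"


_BOND_ORDER = {1: 1.0, 2: 2.0, 3: 3.0, 12: 1.5}


def _pose_from_rdkit(mol, compound_id: str, pose_id: str, native_score: float) -> LigandPose:
    conf = mol.GetConformer()
    atoms = []
    for rd_atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        atoms.append(
            Atom(
                serial=rd_atom.GetIdx(),
                element=rd_atom.GetSymbol().upper(),
                coords=np.array([pos.x, pos.y, pos.z]),
                name=f"{rd_atom.GetSymbol()}{rd_atom.GetIdx() + 1}",
                residue_name="LIG",
                residue_id=1,
                chain="L",
                is_ligand=True,
                formal_charge=rd_atom.GetFormalCharge(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    return LigandPose(
        atoms=atoms,
        bonds=bonds,
        compound_id=compound_id,
        pose_id=pose_id,
        native_score=native_score,
        rdkit_mol=mol,
    )


def read_ligand_poses(
    path: str | Path,
    score_field: str | None = None,
    missing_score: str = "fail",
) -> list[LigandPose]:
    """Read docked ligand poses from an SDF (V2000) or MOL2 file.

    ``score_field`` names the SDF data tag carrying the docking score.
    ``missing_score`` is "fail" (default) or "nan".
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise IOError(f"pose file not found: {path}")
    suffix = path.suffix.lower()
    mols: list = []
    if suffix in (".sdf", ".sd", ".mol"):
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
            mols = [m for m in supplier if m is not None]
        except OSError as exc:  # RDKit raises on empty/invalid input
            raise EmptyStructureError(f"no parseable molecules in {path}: {exc}") from exc
    elif suffix == ".mol2":
        mols = _read_mol2_blocks(path)
    else:
        raise ValueError(f"unsupported pose file format: {suffix}")
    if not mols:
        raise EmptyStructureError(f"no parseable molecules in {path}")

    poses = []
    for idx, mol in enumerate(mols):
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        compound_id = name or f"mol{idx}"
        score = math.nan
        if score_field is not None:
            if mol.HasProp(score_field):
                score = float(mol.GetProp(score_field))
            elif missing_score == "fail":
                raise KeyError(
                    f"record {idx} ({compound_id}) lacks score field '{score_field}'"
                )
        poses.append(_pose_from_rdkit(mol, compound_id, f"{compound_id}_{idx}", score))
    return poses


def _read_mol2_blocks(path: Path) -> list:
    from rdkit import Chem

    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    mols = []
    for block in blocks:
        mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
        if mol is not None:
            mols.append(mol)
    return mols


def assign_vdw_radii(structure, radius_table: dict[str, float] | None = None):
    """Assign van der Waals radii in place (and return the structure).

    Unknown elements get DEFAULT_VDW_RADIUS (1.80 A) with a warning.
    """
    table = {k.upper(): v for k, v in (radius_table or BONDI_RADII).items()}
    unknown: set[str] = set()
    for atom in structure.atoms:
        radius = table.get(atom.element.upper())
        if radius is None:
            radius = DEFAULT_VDW_RADIUS
            unknown.add(atom.element)
        atom.vdw_radius = radius
    if unknown:
        warnings.warn(
            f"elements {sorted(unknown)} missing from radius table; "
            f"using default {DEFAULT_VDW_RADIUS} A",
            stacklevel=2,
        )
    return structure


def extract_binding_site(
    receptor: ReceptorStructure, ligand: LigandPose, cutoff: float = 5.0
) -> ReceptorStructure:
    """Return whole receptor residues with any heavy atom within ``cutoff``
    of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from scipy.spatial import cKDTree

    lig_heavy = np.array([a.coords for a in ligand.atoms if a.element != "H"])
    if lig_heavy.size == 0:
        lig_heavy = ligand.coords()
    tree = cKDTree(lig_heavy)

    keep_keys: set[tuple[str, int, str]] = set()
    for atom in receptor.atoms:
        if atom.element == "H":
            continue
        if tree.query(atom.coords)[0] <= cutoff:
            keep_keys.add((atom.chain, atom.residue_id, atom.residue_name))
    site_atoms = [
        a for a in receptor.atoms if (a.chain, a.residue_id, a.residue_name) in keep_keys
    ]
    if not site_atoms:
        raise EmptyBindingSiteError(
            f"no receptor residue within {cutoff} A of ligand {ligand.compound_id}"
        )
    return ReceptorStructure(atoms=site_atoms, source_id=receptor.source_id)


def assemble_complex(
    receptor_subset: ReceptorStructure, ligand: LigandPose, cutoff_used: float = math.nan
) -> PoseComplex:
    """Assemble a rigid complex; coordinates are never modified (no
    relaxation).  Overlapping serials between the two partners are
    re-indexed on copies, never mutated in place."""
    rec_atoms = [replace(a, coords=a.coords.copy()) for a in receptor_subset.atoms]
    lig_atoms = [replace(a, coords=a.coords.copy()) for a in ligand.atoms]
    rec_serials = {a.serial for a in rec_atoms}
    if rec_serials & {a.serial for a in lig_atoms}:
        next_serial = max(rec_serials) + 1
        for offset, a in enumerate(lig_atoms):
            a.serial = next_serial + offset
    return PoseComplex(
        receptor_subset=ReceptorStructure(atoms=rec_atoms, source_id=receptor_subset.source_id),
        ligand=LigandPose(
            atoms=lig_atoms,
            bonds=list(ligand.bonds),
            compound_id=ligand.compound_id,
            pose_id=ligand.pose_id,
            native_score=ligand.native_score,
            rdkit_mol=ligand.rdkit_mol,
        ),
        cutoff_used=cutoff_used,
    )


def write_structure_pdb(atoms: Sequence[Atom], path: str | Path) -> None:
    """Debug writer: minimal PDB emission for round-trip checks."""
    lines = []
    for atom in atoms:
        record = "HETATM" if atom.is_ligand else "ATOM  "
        x, y, z = atom.coords
        name = atom.name[:4]
        lines.append(
            f"{record}{atom.serial % 100000:5d} {name:<4s}{atom.residue_name[:3]:>4s} "
            f"{(atom.chain or 'A')[:1]}{atom.residue_id % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
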