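"""Pharmacophoric atom typing and per-category SASA sums.

Every atom is assigned exactly one of seven categories so that the seven
per-category SASA sums always partition the total.  The cascade order is
fixed: Negative > Positive > Donor > Acceptor > Aromatic > Hydrophobic >
Other.  Hydrogens inherit the category of their parent heavy atom, which
keeps the partition exact whether or not hydrogens are present.

Ligands are typed with a SMARTS rule file (priority = file order);
receptors with a residue/atom-name lookup table.  Both tables are this
package's own published definitions and are replaceable via the loader
arguments.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sasa import SasaResult
from .structio import LigandPose, ReceptorStructure

CATEGORIES = ("H", "Ar", "D", "Ac", "P", "N", "O")

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class TypingError(ValueError):
    """Raised when a molecule cannot be atom-typed."""


@dataclass
class CategorySums:
    total: float
    per_category: dict[str, float]
    molecule_role: str = ""  # "receptor" | "ligand"
    state: str = ""  # "bound" | "unbound"

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.per_category)
        for cat in missing:
            self.per_category[cat] = 0.0
        if any(v < -1e-9 for v in self.per_category.values()) or self.total < -1e-9:
            raise ValueError("category sums must be non-negative")

    def __getitem__(self, category: str) -> float:
        return self.per_category[category]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ppisasa").joinpath("data", name)))


def load_ligand_rules(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Parse the SMARTS rule file: ``pattern<TAB>category`` per line."""
    path = Path(path) if path else _data_path("ligand_typing.smarts")
    rules = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pattern, category = line.split("\t")
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r} in rule file")
        rules.append((pattern, category))
    return rules


def load_receptor_table(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    path = Path(path) if path else _data_path("receptor_typing.csv")
    table: dict[tuple[str, str], str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[(row["residue"].strip(), row["atom_name"].strip())] = row["category"].strip()
    return table


def type_ligand_atoms(
    ligand: LigandPose, rules: list[tuple[str, str]] | None = None
) -> list[str]:
    """One category per ligand atom via the SMARTS cascade.

    Requires the pose's RDKit molecule (populated by ``read_ligand_poses``).
    Hydrogens inherit from their bonded heavy atom.
    """
    from rdkit import Chem

    mol = ligand.rdkit_mol
    if mol is None:
        raise TypingError(
            f"ligand {ligand.compound_id} has no RDKit molecule; "
            "SMARTS typing needs poses read via read_ligand_poses"
        )
    rules = rules if rules is not None else load_ligand_rules()
    n = mol.GetNumAtoms()
    categories: list[str | None] = [None] * n
    for pattern, category in rules:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise TypingError(f"invalid SMARTS pattern: {pattern}")
        for match in mol.GetSubstructMatches(query, uniquify=True):
            idx = match[0]
            if categories[idx] is None:
                categories[idx] = category
    # hydrogens inherit parent heavy-atom category
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            heavy = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() != 1]
            if heavy:
                categories[atom.GetIdx()] = categories[heavy[0].GetIdx()]
    out = [c if c is not None else "O" for c in categories]
    if len(out) != len(ligand.atoms):
        raise TypingError(
            f"atom count mismatch between pose ({len(ligand.atoms)}) and "
            f"RDKit molecule ({len(out)})"
        )
    return out


def type_receptor_atoms(
    receptor: ReceptorStructure,
    table: dict[tuple[str, str], str] | None = None,
    his_positive: bool = True,
) -> list[str]:
    """One category per receptor atom via residue/atom-name lookup.

    Rules beyond the side-chain table: backbone N -> Donor, backbone O ->
    Acceptor, OXT -> Negative, non-aromatic C and S -> Hydrophobic,
    everything else -> Other.  His ring nitrogens default to Positive
    (doubly-protonatable convention); set ``his_positive=False`` to type
    ND1 as Donor and NE2 as Acceptor instead.  Nonstandard residues fall
    back to element rules with a warning.
    """
    table = table if table is not None else load_receptor_table()
    categories: list[str] = []
    warned: set[str] = set()
    heavy = [(i, a) for i, a in enumerate(receptor.atoms) if a.element != "H"]
    for atom in receptor.atoms:
        if atom.element == "H":
            categories.append("_H_")  # resolved after heavy atoms are typed
            continue
        res, name = atom.residue_name, atom.name
        if res == "HIS" and name in ("ND1", "NE2"):
            if his_positive:
                categories.append("P")
            else:
                categories.append("D" if name == "ND1" else "Ac")
            continue
        cat = table.get((res, name)) or table.get(("*", name))
        if cat is None:
            if res not in _AMINO_ACIDS and res not in warned:
                warnings.warn(
                    f"nonstandard residue {res}: element-based fallback typing",
                    stacklevel=2,
                )
                warned.add(res)
            if name == "N":
                cat = "D"  # backbone amide N
            elif name == "O":
                cat = "Ac"  # backbone carbonyl O
            elif atom.element in ("C", "S"):
                cat = "H"
            else:
                cat = "O"
        categories.append(cat)
    # hydrogens inherit from the nearest heavy atom of the same residue
    for i, atom in enumerate(receptor.atoms):
        if categories[i] != "_H_":
            continue
        same_res = [
            (np.linalg.norm(atom.coords - a.coords), j)
            for j, a in heavy
            if (a.chain, a.residue_id) == (atom.chain, atom.residue_id)
        ]
        pool = same_res or [(np.linalg.norm(atom.coords - a.coords), j) for j, a in heavy]
        categories[i] = categories[min(pool)[1]] if pool else "O"
    return categories


def category_sums(
    sasa: SasaResult | np.ndarray,
    categories: list[str],
    role: str = "",
    state: str = "",
) -> CategorySums:
    """Sum per-atom areas into the seven categories; total = grand sum."""
    areas = sasa.per_atom_area if isinstance(sasa, SasaResult) else np.asarray(sasa, float)
    if len(areas) != len(categories):
        raise ValueError(
            f"length mismatch: {len(areas)} areas vs {len(categories)} categories"
        )
    sums = {c: 0.0 for c in CATEGORIES}
    for area, cat in zip(areas, categories):
        sums[cat] += float(area)
    return CategorySums(
        total=float(np.sum(areas)), per_category=sums, molecule_role=role, state=state
    )
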