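"""Derivation of the 80 bound/unbound SASA descriptors of a docking pose.

For each pharmacophoric category X (T = total, then H, Ar, D, Ac, P, N, O)
and each role M (R = receptor, L = ligand) the descriptor block is

    X_MU   unbound area            X_MB   bound area
    dX_M  = X_MU - X_MB            rel.X_M = X_MB / X_MU

and the 16 combined receptor-ligand descriptors are

    dX_RL  = (X_RU + X_LU) - (X_RB + X_LB)
    rel.X_RL = (X_RB + X_LB) / (X_RU + X_LU)

A zero denominator (no surface of that category exists unbound) yields
rel := 1.0 — "no burial of a nonexistent surface" — and the imputation is
recorded in the vector's ``imputed`` flag set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pharm import CATEGORIES, CategorySums

# T first, then the seven pharmacophoric categories.
DESCRIPTOR_CATEGORIES = ("T",) + CATEGORIES

_NEG_TOL = 1e-6


def descriptor_names() -> list[str]:
    """The 80 descriptor names in canonical order: receptor block, ligand
    block, receptor-ligand block; within each block T, H, Ar, D, Ac, P, N,
    O x (unbound, bound, delta, relative)."""
    names: list[str] = []
    for role in ("R", "L"):
        for x in DESCRIPTOR_CATEGORIES:
            names += [f"{x}_{role}U", f"{x}_{role}B", f"Δ{x}_{role}", f"rel. {x}_{role}"]
    for x in DESCRIPTOR_CATEGORIES:
        names += [f"Δ{x}_RL", f"rel. {x}_RL"]
    return names


@dataclass
class DescriptorVector:
    values: dict[str, float]
    compound_id: str = ""
    pose_id: str = ""
    label: int | None = None
    imputed: frozenset = field(default_factory=frozenset)  # names with rel := 1 imputation

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in descriptor_names()})


def _block(unbound: float, bound: float) -> tuple[float, float, float, float | None]:
    """(U, B, delta, rel); rel is None when U == 0 (imputation handled above)."""
    delta = unbound - bound
    if delta < 0:
        if delta < -_NEG_TOL * max(1.0, unbound):
            warnings.warn(
                f"negative delta {delta:.3g} beyond discretization tolerance; clamping",
                stacklevel=3,
            )
        delta = 0.0
    rel = bound / unbound if unbound > 0 else None
    return unbound, bound, delta, rel


def derive_descriptor_vector(
    receptor_bound: CategorySums,
    receptor_unbound: CategorySums,
    ligand_bound: CategorySums,
    ligand_unbound: CategorySums,
    compound_id: str = "",
    pose_id: str = "",
    label: int | None = None,
) -> DescriptorVector:
    for cs in (receptor_bound, receptor_unbound, ligand_bound, ligand_unbound):
        if cs.total < 0 or any(v < 0 for v in cs.per_category.values()):
            raise ValueError("negative input category sums")

    def cat_value(cs: CategorySums, x: str) -> float:
        return cs.total if x == "T" else cs.per_category[x]

    values: dict[str, float] = {}
    imputed: set[str] = set()
    for role, b_sums, u_sums in (
        ("R", receptor_bound, receptor_unbound),
        ("L", ligand_bound, ligand_unbound),
    ):
        for x in DESCRIPTOR_CATEGORIES:
            u, b, delta, rel = _block(cat_value(u_sums, x), cat_value(b_sums, x))
            rel_name = f"rel. {x}_{role}"
            if rel is None:
                rel = 1.0
                imputed.add(rel_name)
            values[f"{x}_{role}U"] = u
            values[f"{x}_{role}B"] = b
            values[f"Δ{x}_{role}"] = delta
            values[rel_name] = rel
    for x in DESCRIPTOR_CATEGORIES:
        u = cat_value(receptor_unbound, x) + cat_value(ligand_unbound, x)
        b = cat_value(receptor_bound, x) + cat_value(ligand_bound, x)
        _, _, delta, rel = _block(u, b)
        rel_name = f"rel. {x}_RL"
        if rel is None:
            rel = 1.0
            imputed.add(rel_name)
        values[f"Δ{x}_RL"] = delta
        values[rel_name] = rel
    return DescriptorVector(
        values=values,
        compound_id=compound_id,
        pose_id=pose_id,
        label=label,
        imputed=frozenset(imputed),
    )


def descriptor_table(
    vectors: list[DescriptorVector],
    labels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble descriptor vectors into a table, one row per pose.

    ``labels`` maps compound_id -> 0/1 and overrides per-vector labels;
    unlabeled poses get a null label.
    """
    names = descriptor_names()
    columns = ["compound_id", "pose_id"] + names + ["label", "n_imputed"]
    if not vectors:
        return pd.DataFrame(columns=columns)
    keys = [(v.compound_id, v.pose_id) for v in vectors]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (compound_id, pose_id) rows")
    rows = []
    for v in vectors:
        label = labels.get(v.compound_id) if labels is not None else v.label
        row = {"compound_id": v.compound_id, "pose_id": v.pose_id}
        row.update({n: v.values[n] for n in names})
        row["label"] = label if label is not None else np.nan
        row["n_imputed"] = len(v.imputed)
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def pose_descriptors(
    complex_,
    probe: float = 1.4,
    n_points: int = 960,
    receptor_categories: list[str] | None = None,
    ligand_categories: list[str] | None = None,
    label: int | None = None,
) -> DescriptorVector:
    """End-to-end: tri-state SASA + typing + descriptor algebra for one pose.

    Category lists may be injected (synthetic fixtures); otherwise the
    receptor table / ligand SMARTS cascade is applied.
    """
    from .pharm import category_sums, type_ligand_atoms, type_receptor_atoms
    from .sasa import tristate_sasa

    triple = tristate_sasa(complex_, probe=probe, n_points=n_points)
    rec_cats = (
        receptor_categories
        if receptor_categories is not None
        else type_receptor_atoms(complex_.receptor_subset)
    )
    lig_cats = (
        ligand_categories
        if ligand_categories is not None
        else type_ligand_atoms(complex_.ligand)
    )
    rb = category_sums(triple.bound_receptor_areas(), rec_cats, "receptor", "bound")
    ru = category_sums(triple.receptor_unbound, rec_cats, "receptor", "unbound")
    lb = category_sums(triple.bound_ligand_areas(), lig_cats, "ligand", "bound")
    lu = category_sums(triple.ligand_unbound, lig_cats, "ligand", "unbound")
    return derive_descriptor_vector(
        rb, ru, lb, lu,
        compound_id=complex_.ligand.compound_id,
        pose_id=complex_.ligand.pose_id,
        label=label,
    )
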