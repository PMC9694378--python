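"""Synthetic test inputs: pocket-ligand complexes with controllable burial,
two-class descriptor tables with stated effect sizes, and correlated
multi-function score tables.

Every generator is a pure function of its spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import descriptor_names
from .pharm import CATEGORIES
from .rescoring import HIGHER, LOWER, ScoreTable
from .structio import Atom, LigandPose, PoseComplex, ReceptorStructure

_CARBON_RADIUS = 1.70
_PROBE = 1.4


@dataclass
class PocketFixtureSpec:
    n_receptor_atoms: int = 350
    pocket_radius: float = 6.0
    burial_depth: float = 0.0  # 0 = out of contact, 1 = fully enclosed
    ligand_n_atoms: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burial_depth <= 1:
            raise ValueError("burial_depth must be in [0, 1]")
        if self.n_receptor_atoms < 50:
            raise ValueError("need >= 50 receptor atoms for a closed shell")


@dataclass
class SyntheticTableSpec:
    n_active: int = 200
    n_inactive: int = 1800
    n_informative: int = 10
    effect_size: float = 3.0  # standardized mean difference
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active <= 0 or self.n_inactive <= 0:
            raise ValueError("class counts must be positive")
        if not 0 <= self.n_informative <= 80:
            raise ValueError("n_informative must be in [0, 80]")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _ligand_cluster(n: int, rng: np.random.Generator) -> np.ndarray:
    """Small rigid cluster around the origin, extent < ~1.2 A."""
    base = np.array(
        [[0, 0, 0], [1.0, 0, 0], [-0.5, 0.9, 0], [-0.5, -0.9, 0],
         [0, 0, 1.0], [0, 0, -1.0], [0.7, 0.7, 0.5], [-0.7, -0.7, -0.5]]
    ) * 1.1
    if n > len(base):
        extra = rng.normal(scale=0.4, size=(n - len(base), 3))
        base = np.vstack([base, extra])
    return base[:n]


def make_pocket_complex(spec: PocketFixtureSpec) -> PoseComplex:
    """Spherical-shell receptor with an opening that closes as burial depth
    grows; the ligand approaches along the +z pocket axis.

    d = 0: ligand far outside contact range (delta-SASA is zero).
    d in (0, 1]: ligand sits at the shell center and the opening half-angle
    shrinks linearly to zero, so buried area strictly grows with d.
    d = 1: closed cage, ligand bound SASA = 0.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.burial_depth
    lig_coords = _ligand_cluster(spec.ligand_n_atoms, rng)
    extent = float(np.linalg.norm(lig_coords, axis=1).max())
    if extent + 2 * _CARBON_RADIUS >= spec.pocket_radius:
        raise ValueError(
            f"ligand (extent {extent:.1f} A) cannot be enclosed by a pocket "
            f"of radius {spec.pocket_radius} A"
        )

    shell = _fibonacci_sphere(spec.n_receptor_atoms) * spec.pocket_radius
    open_half_angle = math.radians((1.0 - d) * 120.0) if d > 0 else math.radians(120.0)
    # polar angle from +z axis; keep atoms outside the opening cone
    polar = np.arccos(np.clip(shell[:, 2] / spec.pocket_radius, -1, 1))
    shell = shell[polar > open_half_angle]

    z_far = spec.pocket_radius + extent + 2 * (_CARBON_RADIUS + _PROBE) + 2.0
    z_center = z_far if d == 0 else 0.0
    lig_coords = lig_coords + np.array([0.0, 0.0, z_center])

    receptor_atoms = [
        Atom(
            serial=i + 1,
            element="C",
            coords=c,
            vdw_radius=_CARBON_RADIUS,
            name="C1",
            residue_name="PKT",
            residue_id=i + 1,
            chain="A",
        )
        for i, c in enumerate(shell)
    ]
    ligand_atoms = [
        Atom(
            serial=i + 1,
            element="C",
            coords=c,
            vdw_radius=_CARBON_RADIUS,
            name=f"C{i + 1}",
            residue_name="LIG",
            residue_id=1,
            chain="L",
            is_ligand=True,
        )
        for i, c in enumerate(lig_coords)
    ]
    bonds = [(i, i + 1, 1.0) for i in range(len(ligand_atoms) - 1)]
    return PoseComplex(
        receptor_subset=ReceptorStructure(atoms=receptor_atoms, source_id="pocket"),
        ligand=LigandPose(
            atoms=ligand_atoms,
            bonds=bonds,
            compound_id=f"fix{spec.seed}",
            pose_id=f"fix{spec.seed}_d{d:g}",
        ),
    )


def fixture_categories(complex_: PoseComplex, seed: int = 0) -> tuple[list[str], list[str]]:
    """Deterministic injected categories for fixture atoms (bypasses SMARTS
    typing so the descriptor algebra can be tested in isolation)."""
    rng = np.random.default_rng(seed)
    cats = list(CATEGORIES)
    rec = [cats[i] for i in rng.integers(0, len(cats), len(complex_.receptor_subset))]
    lig = [cats[i] for i in rng.integers(0, len(cats), len(complex_.ligand))]
    return rec, lig


def make_descriptor_table(spec: SyntheticTableSpec) -> pd.DataFrame:
    """Two-class 80-column table: the first ``n_informative`` descriptor
    columns carry a class-conditional Gaussian shift of ``effect_size``
    standard deviations; all others are class-independent noise.  Values
    are kept physically plausible (areas >= 0, relative columns in [0, 1])."""
    rng = np.random.default_rng(spec.seed)
    names = descriptor_names()
    n = spec.n_active + spec.n_inactive
    labels = np.concatenate([np.ones(spec.n_active, int), np.zeros(spec.n_inactive, int)])
    data = {}
    informative = set(names[: spec.n_informative])
    for name in names:
        is_rel = name.startswith("rel.")
        if is_rel:
            base, sd = 0.5, 0.1
        else:
            base, sd = 200.0, spec.noise_sd
        col = rng.normal(base, sd, n)
        if name in informative:
            shift = spec.effect_size * sd
            col = col + shift * (labels - 0.5)  # symmetric shift keeps clipping rare
        col = np.clip(col, 0.0, 1.0 if is_rel else None)
        data[name] = col
    frame = pd.DataFrame(data)
    frame.insert(0, "pose_id", [f"cmpd{i}_0" for i in range(n)])
    frame.insert(0, "compound_id", [f"cmpd{i}" for i in range(n)])
    frame["label"] = labels
    # deterministic row shuffle so classes are interleaved
    order = rng.permutation(n)
    return frame.iloc[order].reset_index(drop=True)


def make_score_table(
    n_compounds: int = 200,
    k: int = 6,
    signal: float = 1.0,
    seed: int = 0,
    active_fraction: float = 0.1,
) -> tuple[ScoreTable, pd.Series]:
    """K score columns sharing a latent activity signal, with mixed
    orientations to exercise sign handling.  Returns (table, labels)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    n_active = max(1, int(round(active_fraction * n_compounds)))
    labels = np.zeros(n_compounds, int)
    labels[rng.choice(n_compounds, n_active, replace=False)] = 1
    latent = labels * signal + rng.normal(0, 1, n_compounds)
    frame = pd.DataFrame(
        {
            "compound_id": [f"c{i:04d}" for i in range(n_compounds)],
            "pose_id": [f"c{i:04d}_0" for i in range(n_compounds)],
        }
    )
    orientations = {}
    for j in range(k):
        col = f"score{j}"
        noise = rng.normal(0, 1, n_compounds)
        values = latent + noise
        if j % 2 == 1:  # alternate orientations
            values = -values
            orientations[col] = LOWER
        else:
            orientations[col] = HIGHER
        frame[col] = values
    frame["label"] = labels
    return ScoreTable(frame=frame, orientations=orientations), pd.Series(labels)
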