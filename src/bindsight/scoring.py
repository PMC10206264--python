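"""Ensemble scoring of designed compounds against receptor conformations.

A compound is scored against every member of a receptor ensemble (the
cluster-medoid structures) and the per-member scores are aggregated by
minimum — the most favorable (most negative, kcal/mol) binding energy
across conformations.  Scorers are pluggable: a table-backed scorer wraps
externally computed docking results, and a deterministic surrogate
(single-point interaction energy with a distance-dependent dielectric)
lets the whole pipeline run without any external docking engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .design import CompoundSpec
from .gbsa import COULOMB, GBParams, MIN_PAIR_DISTANCE, sasa
from .structures import Atom, Structure

__all__ = [
    "ReceptorEnsemble",
    "ScoreRecord",
    "Scorer",
    "score_compound",
    "surrogate_score",
    "SurrogateScorer",
    "rank_and_shortlist",
    "load_score_table",
    "write_score_table",
    "TableScorer",
    "pose_from_smiles",
]

SHORTLIST_THRESHOLD = -10.00  # kcal/mol


@dataclass
class ReceptorEnsemble:
    """Labelled receptor conformations (typically cluster medoids)."""

    members: list[tuple[str, Structure]]
    populations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        labels = [lbl for lbl, _ in self.members]
        if len(set(labels)) != len(labels):
            raise ValueError("ensemble member labels must be unique")


@dataclass
class ScoreRecord:
    """Per-member scores (kcal/mol) and their minimum aggregate."""

    name: str
    per_member: dict[str, float]
    aggregate: float
    failed_members: list[str] = field(default_factory=list)


class Scorer(Protocol):
    """Scores one (compound, ensemble member) pair; ``None`` declares
    failure for that pair."""

    def __call__(self, compound: CompoundSpec, member_label: str,
                 receptor: Structure) -> float | None: ...


def score_compound(compound: CompoundSpec, ensemble: ReceptorEnsemble,
                   scorer: Scorer) -> ScoreRecord:
    """Score against every ensemble member; aggregate = min over the
    successful members.  Raises if every member fails."""
    per_member: dict[str, float] = {}
    failed = []
    for label, receptor in ensemble.members:
        value = scorer(compound, label, receptor)
        if value is None:
            failed.append(label)
        else:
            per_member[label] = float(value)
    if not per_member:
        raise RuntimeError(
            f"compound {compound.name}: all ensemble members failed to score")
    return ScoreRecord(name=compound.name, per_member=per_member,
                       aggregate=min(per_member.values()),
                       failed_members=failed)


# ---------------------------------------------------------------------------
# Surrogate scorer
# ---------------------------------------------------------------------------

def surrogate_score(compound_pose: Structure, receptor: Structure,
                    params: GBParams = GBParams()) -> float | None:
    """Deterministic single-point interaction score (kcal/mol).

    Intermolecular Lennard-Jones plus Coulomb with a distance-dependent
    dielectric eps(r) = 4r, plus the surface term gamma * dSASA on
    complexation.  No pose search is performed; a clash (pair closer than
    0.5 A) is a declared failure (returns ``None``), not an exception.
    """
    lig_pos = compound_pose.coords
    rec_pos = receptor.coords
    r = np.linalg.norm(rec_pos[:, None, :] - lig_pos[None, :, :], axis=-1)
    if r.size == 0:
        return 0.0
    if r.min() < MIN_PAIR_DISTANCE:
        return None
    sig = 0.5 * (receptor.array("lj_sigma")[:, None]
                 + compound_pose.array("lj_sigma")[None, :])
    eps = np.sqrt(receptor.array("lj_epsilon")[:, None]
                  * compound_pose.array("lj_epsilon")[None, :])
    sr6 = (sig / r) ** 6
    e_vdw = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    q = receptor.charges[:, None] * compound_pose.charges[None, :]
    e_ele = float(np.sum(COULOMB * q / (4.0 * r * r)))  # eps(r) = 4r

    combined = _combine_structures(receptor, compound_pose)
    coords = combined.coords
    n_rec = receptor.n_atoms
    s_c = sasa(combined, coords, probe_radius=params.probe_radius,
               n_points=params.sasa_points)[1]
    s_r = sasa(combined, coords, group=np.arange(n_rec),
               probe_radius=params.probe_radius, n_points=params.sasa_points)[1]
    s_l = sasa(combined, coords, group=np.arange(n_rec, combined.n_atoms),
               probe_radius=params.probe_radius, n_points=params.sasa_points)[1]
    e_surf = params.surface_tension * (s_c - s_r - s_l)
    return e_vdw + e_ele + e_surf


def _combine_structures(receptor: Structure, ligand: Structure) -> Structure:
    atoms = []
    for a in receptor.atoms + ligand.atoms:
        atoms.append(Atom(serial=len(atoms) + 1, name=a.name,
                          element=a.element, residue_name=a.residue_name,
                          residue_index=a.residue_index, chain_id=a.chain_id,
                          position=a.position.copy(), charge=a.charge,
                          lj_sigma=a.lj_sigma, lj_epsilon=a.lj_epsilon,
                          mass=a.mass, gb_radius=a.gb_radius,
                          is_backbone=a.is_backbone))
    n_rec = receptor.n_atoms
    return Structure(atoms=atoms, groups={
        "receptor": set(range(n_rec)),
        "ligand": set(range(n_rec, len(atoms)))})


# element -> (sigma A, epsilon kcal/mol, mass amu, born radius A) used for
# generated poses
_POSE_PARAMS = {
    "H": (1.07, 0.016, 1.008, 1.20),
    "C": (3.40, 0.109, 12.011, 1.70),
    "N": (3.25, 0.170, 14.007, 1.55),
    "O": (2.96, 0.210, 15.999, 1.50),
    "F": (3.12, 0.061, 18.998, 1.47),
    "S": (3.56, 0.250, 32.06, 1.80),
    "CL": (3.47, 0.265, 35.45, 1.75),
    "BR": (3.60, 0.320, 79.904, 1.85),
}


def pose_from_smiles(smiles: str, center: np.ndarray, seed: int = 0,
                     name: str = "LIG") -> Structure:
    """Deterministic heavy-atom 3-D pose for a SMILES string.

    One ETKDG conformer (fixed seed) translated so its centroid sits at
    ``center``; Gasteiger partial charges, element-based LJ parameters.
    This is pose *generation* plumbing for the surrogate scorer, not a
    docking search.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"conformer generation failed for {smiles!r}")
    AllChem.ComputeGasteigerCharges(mol)
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z]
                       for i in range(mol.GetNumAtoms())])
    coords = coords - coords.mean(axis=0) + np.asarray(center, dtype=float)
    atoms = []
    for i, rd_atom in enumerate(mol.GetAtoms()):
        element = rd_atom.GetSymbol().upper()
        sig, eps, mass, rgb = _POSE_PARAMS.get(element, (3.4, 0.1, 12.0, 1.7))
        charge = float(rd_atom.GetDoubleProp("_GasteigerCharge"))
        if not np.isfinite(charge):
            charge = 0.0
        atoms.append(Atom(serial=i + 1, name=f"{rd_atom.GetSymbol()}{i + 1}",
                          element=rd_atom.GetSymbol(), residue_name=name,
                          residue_index=1, chain_id="B", position=coords[i],
                          charge=charge, lj_sigma=sig, lj_epsilon=eps,
                          mass=mass, gb_radius=rgb))
    return Structure(atoms=atoms,
                     groups={"ligand": set(range(len(atoms)))})


@dataclass
class SurrogateScorer:
    """Scorer adapter: generates one deterministic pose per compound at the
    pocket center and evaluates :func:`surrogate_score`.

    The pose is rigidly backed away from the receptor along the
    receptor-to-pocket axis until the closest contact reaches
    ``min_contact`` — deterministic placement plumbing, not a pose search.
    """

    pocket_center: np.ndarray
    params: GBParams = field(default_factory=GBParams)
    seed: int = 0
    min_contact: float = 2.8  # A, near the LJ contact minimum
    _pose_cache: dict[str, Structure] = field(default_factory=dict, repr=False)

    def __call__(self, compound: CompoundSpec, member_label: str,
                 receptor: Structure) -> float | None:
        pose = self._pose_cache.get(compound.smiles)
        if pose is None:
            pose = pose_from_smiles(compound.smiles, self.pocket_center,
                                    seed=self.seed)
            self._pose_cache[compound.smiles] = pose
        rec_coords = receptor.coords
        axis = np.asarray(self.pocket_center) - rec_coords.mean(axis=0)
        axis = axis / np.linalg.norm(axis)
        lig_coords = pose.coords
        for _ in range(200):
            d = np.linalg.norm(rec_coords[:, None] - lig_coords[None, :],
                               axis=-1)
            if d.min() >= self.min_contact:
                break
            lig_coords = lig_coords + 0.25 * axis
        placed = pose.copy()
        placed.set_coords(lig_coords)
        return surrogate_score(placed, receptor, self.params)


# ---------------------------------------------------------------------------
# Table-backed scorer
# ---------------------------------------------------------------------------

@dataclass
class TableScorer:
    """Exact lookup of externally computed (compound, member) scores;
    a missing pair is a declared failure."""

    table: dict[tuple[str, str], float]

    def __call__(self, compound: CompoundSpec, member_label: str,
                 receptor: Structure | None = None) -> float | None:
        return self.table.get((compound.name, member_label))


def load_score_table(path: str | Path) -> TableScorer:
    """Parse a TSV of ``compound<TAB>member<TAB>score`` rows."""
    table: dict[tuple[str, str], float] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.split("\t")[:2] == ["compound", "member"]:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        key = (parts[0], parts[1])
        if key in table:
            raise ValueError(f"{path}:{lineno}: duplicate pair {key}")
        try:
            table[key] = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
    return TableScorer(table)


def write_score_table(scorer_or_table, path: str | Path) -> None:
    table = (scorer_or_table.table if isinstance(scorer_or_table, TableScorer)
             else dict(scorer_or_table))
    lines = ["compound\tmember\tscore"]
    for (comp, member), score in table.items():
        lines.append(f"{comp}\t{member}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_and_shortlist(records: list[ScoreRecord],
                       threshold: float = SHORTLIST_THRESHOLD
                       ) -> tuple[list[ScoreRecord], list[ScoreRecord]]:
    """Ascending sort by aggregate (ties by name); shortlist keeps records
    at or below the threshold (default -10.00 kcal/mol)."""
    ranked = sorted(records, key=lambda r: (r.aggregate, r.name))
    shortlist = [r for r in ranked if r.aggregate <= threshold]
    return ranked, shortlist
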