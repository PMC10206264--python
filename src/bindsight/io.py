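"""Reading and writing structures, trajectories, topology files and tables.

PDB files (single- and multi-model, wwPDB fixed-width columns) are handled
through :mod:`biotite`; force-field parameters come from a plain-text
topology file with one atom record per line::

    # residue  atom  element  charge  lj_sigma  lj_epsilon  mass  gb_radius  backbone
    ALA        N     N        -0.4157 3.2500    0.1700      14.007 1.55      1

keyed by ``(residue_name, atom_name)``.  Tabular reports are TSV with a
header, energies at 2 decimals and a deterministic row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .structures import Atom, Structure, Trajectory, BACKBONE_ATOM_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyEntry",
    "read_topology",
    "write_topology",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class TopologyEntry:
    residue_name: str
    atom_name: str
    element: str
    charge: float
    lj_sigma: float
    lj_epsilon: float
    mass: float
    gb_radius: float
    is_backbone: bool


TopologyTable = dict[tuple[str, str], TopologyEntry]

_TOPOLOGY_HEADER = (
    "# residue atom element charge lj_sigma lj_epsilon mass gb_radius backbone"
)


def read_topology(path: str | Path) -> TopologyTable:
    """Parse a topology text file into a ``(residue, atom) -> entry`` map."""
    table: TopologyTable = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 9:
            raise ValueError(
                f"{path}:{lineno}: expected 9 fields, got {len(parts)}")
        res, name, element = parts[0], parts[1], parts[2]
        entry = TopologyEntry(
            residue_name=res,
            atom_name=name,
            element=element,
            charge=float(parts[3]),
            lj_sigma=float(parts[4]),
            lj_epsilon=float(parts[5]),
            mass=float(parts[6]),
            gb_radius=float(parts[7]),
            is_backbone=parts[8] not in ("0", "false", "False"),
        )
        key = (res, name)
        if key in table:
            raise ValueError(f"{path}:{lineno}: duplicate topology entry {key}")
        table[key] = entry
    return table


def write_topology(entries: Iterable[TopologyEntry], path: str | Path) -> None:
    lines = [_TOPOLOGY_HEADER]
    for e in entries:
        lines.append(
            f"{e.residue_name} {e.atom_name} {e.element} {e.charge:.4f} "
            f"{e.lj_sigma:.4f} {e.lj_epsilon:.4f} {e.mass:.4f} "
            f"{e.gb_radius:.4f} {1 if e.is_backbone else 0}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def topology_from_structure(structure: Structure) -> list[TopologyEntry]:
    """Topology records for every distinct (residue, atom) in a structure."""
    seen: dict[tuple[str, str], TopologyEntry] = {}
    for a in structure.atoms:
        key = (a.residue_name, a.name)
        seen.setdefault(key, TopologyEntry(
            residue_name=a.residue_name, atom_name=a.name, element=a.element,
            charge=a.charge, lj_sigma=a.lj_sigma, lj_epsilon=a.lj_epsilon,
            mass=a.mass, gb_radius=a.gb_radius, is_backbone=a.is_backbone,
        ))
    return list(seen.values())


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

# default covalent-bond detection cutoffs (Angstrom) used when no bond
# table is available; generous enough for jittered synthetic geometries
_BOND_CUTOFF_HEAVY = 1.9
_BOND_CUTOFF_H = 1.3


def _infer_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    coords = np.array([a.position for a in atoms])
    is_h = np.array([a.element == "H" for a in atoms])
    bonds = []
    n = len(atoms)
    if n < 2:
        return bonds
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = _BOND_CUTOFF_H if (is_h[i] or is_h[j]) else _BOND_CUTOFF_HEAVY
            if is_h[i] and is_h[j]:
                continue
            if d[i, j] < cutoff:
                bonds.append((i, j))
    return bonds


def _atoms_from_atom_array(array: bst.AtomArray, topology: TopologyTable,
                           allow_missing: bool) -> list[Atom]:
    atoms = []
    missing = []
    for i in range(array.array_length()):
        res = str(array.res_name[i]).strip()
        name = str(array.atom_name[i]).strip()
        entry = topology.get((res, name))
        if entry is None:
            missing.append(f"{res}/{name}")
            if not allow_missing:
                continue
            element = str(array.element[i]).strip() or name[0]
            entry = TopologyEntry(res, name, element, 0.0, 0.0, 0.0,
                                  _ELEMENT_MASSES.get(element, 12.0), 1.5,
                                  name in BACKBONE_ATOM_NAMES)
        atoms.append(Atom(
            serial=i + 1,
            name=name,
            element=entry.element,
            residue_name=res,
            residue_index=int(array.res_id[i]),
            chain_id=str(array.chain_id[i]).strip() or "A",
            position=array.coord[i],
            charge=entry.charge,
            lj_sigma=entry.lj_sigma,
            lj_epsilon=entry.lj_epsilon,
            mass=entry.mass,
            gb_radius=entry.gb_radius,
            is_backbone=entry.is_backbone,
        ))
    if missing:
        if allow_missing:
            logger.warning(
                "%d atoms had no topology entry (charge/LJ zeroed): %s",
                len(missing), ", ".join(missing[:10]))
        else:
            raise ValueError(
                "atoms with no topology entry: " + ", ".join(missing))
    return atoms


_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                   "F": 18.998, "P": 30.974, "S": 32.06, "CL": 35.45}


def read_structure(path: str | Path, topology_path: str | Path,
                   allow_missing: bool = False) -> Structure:
    """Read a (single-model) PDB file and parameterize it from a topology.

    Receptor/ligand groups are assigned from the PDB record type: ATOM
    records form the ``"receptor"`` group, HETATM records the ``"ligand"``
    group.  Bonds are inferred from interatomic distances.
    """
    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(model=1)
    atoms = _atoms_from_atom_array(array, read_topology(topology_path),
                                   allow_missing)
    hetero = np.asarray(array.hetero, dtype=bool)
    groups = {
        "receptor": {i for i in range(len(atoms)) if not hetero[i]},
        "ligand": {i for i in range(len(atoms)) if hetero[i]},
    }
    groups = {k: v for k, v in groups.items() if v}
    return Structure(atoms=atoms, bonds=_infer_bonds(atoms), groups=groups)


def _atom_array_from_structure(structure: Structure,
                               coords: np.ndarray | None = None) -> bst.AtomArray:
    n = structure.n_atoms
    array = bst.AtomArray(n)
    ligand = structure.groups.get("ligand", set())
    for i, a in enumerate(structure.atoms):
        array.chain_id[i] = a.chain_id
        array.res_id[i] = a.residue_index
        array.res_name[i] = a.residue_name
        array.atom_name[i] = a.name
        array.element[i] = a.element
        array.hetero[i] = i in ligand
    array.coord = (structure.coords if coords is None
                   else np.asarray(coords, dtype=float))
    return array


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (fixed-width wwPDB columns)."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure))
    pdb.write(str(path))


def read_trajectory(path: str | Path, structure: Structure,
                    dt: float = 1.0, start_time: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory over ``structure``'s roster.

    Frame times are assigned uniformly (``start_time + k * dt`` ps) since
    the PDB format carries none.  Any MODEL whose atom count differs from
    the roster raises an error citing the model number.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = []
    for m in range(1, n_models + 1):
        array = pdb.get_structure(model=m)
        if array.array_length() != structure.n_atoms:
            raise ValueError(
                f"model {m}: has {array.array_length()} atoms, expected "
                f"{structure.n_atoms}")
        frames.append(array.coord)
    times = start_time + dt * np.arange(n_models)
    return Trajectory(structure=structure, frames=np.array(frames),
                      frame_times=times, native_dt=dt)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    n = traj.structure.n_atoms
    template = _atom_array_from_structure(traj.structure)
    stack = bst.AtomArrayStack(traj.n_frames, n)
    for annot in ("chain_id", "res_id", "res_name", "atom_name", "element",
                  "hetero"):
        stack.set_annotation(annot, template.get_annotation(annot))
    stack.coord = traj.frames
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _record_to_dict(rec) -> dict:
    if is_dataclass(rec) and not isinstance(rec, type):
        return {f.name: getattr(rec, f.name) for f in dc_fields(rec)}
    if isinstance(rec, Mapping):
        return dict(rec)
    raise TypeError(f"cannot convert record of type {type(rec)!r} to a row")


def write_table(records: Sequence, path: str | Path,
                sort_key: str | None = None,
                columns: Sequence[str] | None = None) -> None:
    """Write uniform records as TSV: header always present, floats at 2
    decimals, rows stably sorted by ``sort_key`` when given."""
    rows = [_record_to_dict(r) for r in records]
    if rows:
        field_sets = {tuple(r.keys()) for r in rows}
        if len(field_sets) > 1:
            raise ValueError("records do not share a single field set")
    df = pd.DataFrame(rows, columns=columns if columns is not None
                      else (list(rows[0].keys()) if rows else []))
    if sort_key is not None and len(df):
        df = df.sort_values(sort_key, kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
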