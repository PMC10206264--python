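"""Shared data model: atoms, structures, trajectories and analysis windows.

Units follow the conventions used throughout the package: coordinates in
Angstrom, partial charges in elementary charges, energies in kcal/mol,
masses in amu, times in ps.  Frame indices are 0-based internally and
1-based in written reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AnalysisWindow",
    "ResidueKey",
]

#: Residue identity as it appears in the input PDB: (chain_id, residue_index,
#: residue_name).  No renumbering is ever applied.
ResidueKey = tuple[str, int, str]

# Protein backbone atom names; H/HA included when present.  Everything else
# is side chain.  Ligand atoms are never backbone.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "H", "HA"})


@dataclass
class Atom:
    """A single atom with coordinates and force-field parameters.

    ``lj_sigma``/``lj_epsilon`` are Lennard-Jones parameters (Angstrom,
    kcal/mol), ``gb_radius`` the intrinsic Born radius used by the
    generalized-Born solvation model.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    mass: float = 1.0
    gb_radius: float = 1.5
    is_backbone: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: negative LJ parameters")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index, self.residue_name)


@dataclass
class Structure:
    """An ordered atom roster with bonds and named atom groups.

    ``groups`` maps a name (e.g. ``"receptor"``, ``"ligand"``, region tags)
    to a set of 0-based atom indices.  The receptor and ligand groups must
    be disjoint.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    groups: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) references invalid atom index")
        rec = self.groups.get("receptor", set())
        lig = self.groups.get("ligand", set())
        if rec & lig:
            raise ValueError("receptor and ligand groups overlap")
        for name, members in self.groups.items():
            bad = [i for i in members if not 0 <= i < n]
            if bad:
                raise ValueError(f"group {name!r} has invalid indices {bad}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    # -- vectorized parameter views (cheap for desk-scale systems) --------
    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return self.array("charge")

    @property
    def masses(self) -> np.ndarray:
        return self.array("mass")

    def group_indices(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"structure has no group {name!r}")
        return np.array(sorted(self.groups[name]), dtype=int)

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.residue_key, None)
        return list(seen)

    def subset(self, indices: np.ndarray) -> "Structure":
        """New Structure containing only ``indices`` (order preserved);
        bonds inside the subset are kept, groups restricted and reindexed."""
        indices = np.asarray(indices, dtype=int)
        mapping = {int(old): new for new, old in enumerate(indices)}
        atoms = [replace(self.atoms[i], position=self.atoms[i].position.copy())
                 for i in indices]
        bonds = [(mapping[a], mapping[b]) for a, b in self.bonds
                 if a in mapping and b in mapping]
        groups = {}
        for name, members in self.groups.items():
            kept = {mapping[i] for i in members if i in mapping}
            if kept:
                groups[name] = kept
        return Structure(atoms=atoms, bonds=bonds, groups=groups)

    def copy(self) -> "Structure":
        return self.subset(np.arange(self.n_atoms))


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom roster."""

    structure: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray  # ps, strictly increasing
    #: native sampling interval of the source trajectory (ps); preserved by
    #: window selection so that striding is anchored to the original grid.
    native_dt: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, structure has "
                f"{self.structure.n_atoms}"
            )
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length mismatch")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.native_dt is None and len(self.frame_times) > 1:
            self.native_dt = float(np.min(np.diff(self.frame_times)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms


@dataclass(frozen=True)
class AnalysisWindow:
    """A time window [start_time, end_time] (ps) with a frame stride."""

    start_time: float
    end_time: float
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.start_time < self.end_time:
            raise ValueError("window start must precede end")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @classmethod
    def last_fraction(cls, traj: Trajectory, fraction: float, stride: int = 1
                      ) -> "AnalysisWindow":
        """Window covering the last ``fraction`` of the trajectory's span."""
        t0, t1 = float(traj.frame_times[0]), float(traj.frame_times[-1])
        return cls(start_time=t1 - fraction * (t1 - t0), end_time=t1,
                   stride=stride)


def select_window(traj: Trajectory, window: AnalysisWindow) -> Trajectory:
    """Frames with start <= t <= end, subsampled by stride.

    Striding is anchored to the trajectory's native sampling grid, so
    applying the same window twice equals applying it once (idempotence).
    Raises ``ValueError`` on an empty selection.
    """
    mask = (traj.frame_times >= window.start_time) & (
        traj.frame_times <= window.end_time)
    idx = np.nonzero(mask)[0]
    if window.stride > 1 and len(idx) > 0 and traj.native_dt:
        # position of each selected frame on the native time grid, counted
        # from the first selected frame
        t0 = traj.frame_times[idx[0]]
        pos = np.rint((traj.frame_times[idx] - t0) / traj.native_dt).astype(int)
        idx = idx[pos % window.stride == 0]
    elif window.stride > 1:
        idx = idx[:: window.stride]
    if len(idx) == 0:
        raise ValueError(
            f"window [{window.start_time}, {window.end_time}] ps selects no "
            f"frames from trajectory spanning "
            f"[{traj.frame_times[0]}, {traj.frame_times[-1]}] ps"
        )
    return Trajectory(
        structure=traj.structure,
        frames=traj.frames[idx].copy(),
        frame_times=traj.frame_times[idx].copy(),
        native_dt=traj.native_dt,
    )
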