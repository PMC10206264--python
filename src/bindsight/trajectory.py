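"""Trajectory stability metrics, hydrogen-bond occupancy and clustering.

Implements the standard MD post-processing toolbox used to characterise an
inhibitor/kinase complex: least-squares (Kabsch) superposition, RMSD and
per-residue RMSF series, geometric monitors (distances and angles),
hydrogen-bond detection with occupancy statistics, and average-linkage
hierarchical clustering of frames on a pairwise-RMSD matrix with medoid
(centroid-frame) representatives.

The hydrogen-bond criterion follows the common CPPTRAJ-style definition:
donor-acceptor distance strictly below 3.5 A and acceptor-H-donor angle
(vertex at the hydrogen) strictly above 120 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures import ResidueKey, Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "ClusterResult",
    "superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "detect_hbonds",
    "hbond_count_series",
    "monitor_geometry",
    "GeometrySeries",
    "cluster_frames",
]


# ---------------------------------------------------------------------------
# Superposition and deviation metrics
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              atom_subset: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over the
    subset.  The rotation is always proper (det = +1).

    Raises ``ValueError`` for subsets smaller than 3 atoms or collinear
    reference geometry.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if atom_subset is None else np.asarray(atom_subset)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    m = mobile[sel]
    r = reference[sel]
    mc = m - m.mean(axis=0)
    rc = r - r.mean(axis=0)
    if np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom subset")
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = r.mean(axis=0) - rotation @ m.mean(axis=0)
    moved = m @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def rmsd_series(traj: Trajectory, atom_subset: np.ndarray,
                reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (A) to a reference frame after superposition on the
    subset."""
    ref = traj.frames[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = superpose(traj.frames[f], ref, atom_subset)
    return out


def _iterated_mean_fit(frames: np.ndarray, atom_subset: np.ndarray,
                       passes: int = 2) -> np.ndarray:
    """Superpose all frames to their running mean structure (2 passes)."""
    aligned = frames.copy()
    ref = aligned[0]
    for _ in range(passes):
        for f in range(len(aligned)):
            rot, trans, _ = superpose(aligned[f], ref, atom_subset)
            aligned[f] = apply_transform(aligned[f], rot, trans)
        ref = aligned.mean(axis=0)
    return aligned


def rmsf_per_residue(traj: Trajectory, atom_subset: np.ndarray
                     ) -> dict[ResidueKey, float]:
    """Root-mean-square fluctuation per residue (A).

    Frames are first superposed to their mean structure (iterated mean
    fit, two passes) over the subset; RMSF_i = sqrt(<|r_i - <r_i>|^2>) per
    selected atom, then averaged over each residue's selected atoms.
    """
    atom_subset = np.asarray(atom_subset, dtype=int)
    if len(atom_subset) == 0:
        raise ValueError("empty atom subset")
    aligned = _iterated_mean_fit(traj.frames, atom_subset)
    mean = aligned.mean(axis=0)
    msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)  # per atom
    per_res: dict[ResidueKey, list[float]] = {}
    for i in atom_subset:
        key = traj.structure.atoms[i].residue_key
        per_res.setdefault(key, []).append(float(np.sqrt(msf[i])))
    return {k: float(np.mean(v)) for k, v in per_res.items()}


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (strict inequalities)."""

    max_donor_acceptor_distance: float = 3.5  # A
    min_angle_at_hydrogen: float = 120.0  # degrees, vertex at H

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_angle_at_hydrogen < 180:
            raise ValueError("angle cutoff must lie in (0, 180)")


@dataclass
class HBondRecord:
    """Occupancy statistics of one donor-H...acceptor triple."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_label: str
    acceptor_label: str
    occupancy: float  # percent of frames
    per_frame_flags: np.ndarray = field(repr=False)
    mean_distance: float = 0.0
    sd_distance: float = 0.0
    mean_angle: float = 0.0
    sd_angle: float = 0.0


_DONOR_ELEMENTS = ("N", "O", "S")
_ACCEPTOR_ELEMENTS = ("N", "O")
_H_ATTACH_CUTOFF = 1.2  # A, fallback when no bond table is available


def _atom_label(structure: Structure, i: int) -> str:
    a = structure.atoms[i]
    return f"{a.chain_id}:{a.residue_name}{a.residue_index}@{a.name}"


def _attached_hydrogens(structure: Structure, donor: int) -> list[int]:
    hs = [j for a, b in structure.bonds
          for d, j in ((a, b), (b, a))
          if d == donor and structure.atoms[j].element == "H"]
    if hs:
        return sorted(set(hs))
    # fall back to proximity in the reference coordinates
    pos = structure.atoms[donor].position
    return [j for j, at in enumerate(structure.atoms)
            if at.element == "H"
            and np.linalg.norm(at.position - pos) < _H_ATTACH_CUTOFF]


def _default_donors(structure: Structure, indices: np.ndarray) -> list[int]:
    return [int(i) for i in indices
            if structure.atoms[i].element in _DONOR_ELEMENTS
            and _attached_hydrogens(structure, int(i))]


def _default_acceptors(structure: Structure, indices: np.ndarray) -> list[int]:
    return [int(i) for i in indices
            if structure.atoms[i].element in _ACCEPTOR_ELEMENTS]


def _angle_at_vertex(a: np.ndarray, vertex: np.ndarray, b: np.ndarray
                     ) -> np.ndarray:
    """Angle (degrees) a-vertex-b for arrays of frames."""
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(traj: Trajectory,
                  criteria: HBondCriteria = HBondCriteria(),
                  donors: list[int] | None = None,
                  acceptors: list[int] | None = None,
                  intermolecular: bool = True,
                  reporting_floor: float = 5.0) -> list[HBondRecord]:
    """Hydrogen-bond occupancy over a trajectory.

    A frame counts as bonded when d(donor, acceptor) < cutoff AND the
    acceptor-H-donor angle (vertex at H) exceeds the angle cutoff.  Donors
    without an attached hydrogen are skipped with a warning.  With
    ``intermolecular=True`` (the default) only donor/acceptor pairs lying
    in different receptor/ligand groups are examined.  Records with
    occupancy at or above ``reporting_floor`` (percent) are returned,
    sorted by descending occupancy.
    """
    s = traj.structure
    rec = s.groups.get("receptor", set())
    lig = s.groups.get("ligand", set())
    all_idx = np.arange(s.n_atoms)
    donor_list = donors if donors is not None else _default_donors(s, all_idx)
    acceptor_list = (acceptors if acceptors is not None
                     else _default_acceptors(s, all_idx))

    records = []
    for d in donor_list:
        hydrogens = _attached_hydrogens(s, d)
        if not hydrogens:
            logger.warning("donor %s has no attached hydrogen; skipped",
                           _atom_label(s, d))
            continue
        for acc in acceptor_list:
            if acc == d or acc in hydrogens:
                continue
            if intermolecular and not (
                    (d in rec and acc in lig) or (d in lig and acc in rec)):
                continue
            for h in hydrogens:
                dist = np.linalg.norm(
                    traj.frames[:, d] - traj.frames[:, acc], axis=1)
                ang = _angle_at_vertex(traj.frames[:, acc],
                                       traj.frames[:, h],
                                       traj.frames[:, d])
                flags = (dist < criteria.max_donor_acceptor_distance) & (
                    ang > criteria.min_angle_at_hydrogen)
                occ = 100.0 * flags.mean()
                if occ < reporting_floor:
                    continue
                records.append(HBondRecord(
                    donor_index=d, hydrogen_index=h, acceptor_index=acc,
                    donor_label=_atom_label(s, d),
                    acceptor_label=_atom_label(s, acc),
                    occupancy=float(occ), per_frame_flags=flags,
                    mean_distance=float(dist.mean()),
                    sd_distance=float(dist.std()),
                    mean_angle=float(ang.mean()),
                    sd_angle=float(ang.std())))
    records.sort(key=lambda r: (-r.occupancy, r.donor_index, r.acceptor_index))
    return records


def hbond_count_series(traj: Trajectory,
                       criteria: HBondCriteria = HBondCriteria()
                       ) -> tuple[np.ndarray, float, float]:
    """Per-frame count of intermolecular hydrogen bonds, with mean +/- sd."""
    records = detect_hbonds(traj, criteria, intermolecular=True,
                            reporting_floor=0.0)
    counts = np.zeros(traj.n_frames, dtype=int)
    for r in records:
        counts += r.per_frame_flags.astype(int)
    return counts, float(counts.mean()), float(counts.std())


# ---------------------------------------------------------------------------
# Geometric monitors
# ---------------------------------------------------------------------------

@dataclass
class GeometrySeries:
    """Per-frame distance (A) or angle (degrees) for one probe."""

    indices: tuple[int, ...]
    kind: str  # "distance" | "angle"
    values: np.ndarray = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0


def monitor_geometry(traj: Trajectory,
                     probes: list[tuple[int, ...]]) -> list[GeometrySeries]:
    """Euclidean distances for atom pairs, angles (at the middle atom) for
    triples."""
    out = []
    n = traj.structure.n_atoms
    for probe in probes:
        if any(not 0 <= i < n for i in probe):
            raise IndexError(f"probe {probe} references an invalid atom index")
        if len(probe) == 2:
            i, j = probe
            vals = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)
            kind = "distance"
        elif len(probe) == 3:
            i, j, k = probe
            vals = _angle_at_vertex(traj.frames[:, i], traj.frames[:, j],
                                    traj.frames[:, k])
            kind = "angle"
        else:
            raise ValueError("probes must be atom pairs or triples")
        out.append(GeometrySeries(indices=tuple(probe), kind=kind, values=vals,
                                  mean=float(vals.mean()), sd=float(vals.std())))
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Average-linkage clustering of trajectory frames on pairwise RMSD."""

    labels: np.ndarray  # cluster id (1-based) per analysed frame
    frame_indices: np.ndarray  # original frame index of each analysed frame
    populations: dict[int, float]  # percent per cluster
    counts: dict[int, int]  # frame count per cluster
    representative_frames: dict[int, int]  # medoid original frame index

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError("cluster populations must sum to 100")


def pairwise_rmsd_matrix(traj: Trajectory, atom_subset: np.ndarray,
                         frame_indices: np.ndarray) -> np.ndarray:
    m = len(frame_indices)
    mat = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            _, _, r = superpose(traj.frames[frame_indices[a]],
                                traj.frames[frame_indices[b]], atom_subset)
            mat[a, b] = mat[b, a] = r
    return mat


def cluster_frames(traj: Trajectory, atom_subset: np.ndarray,
                   n_clusters: int, stride: int = 1) -> ClusterResult:
    """Hierarchical average-linkage clustering cut to ``n_clusters``.

    The representative of each cluster is its medoid: the member frame
    minimising the summed pairwise RMSD to all other members.  Populations
    are reported both as percent and as frame counts.  Deterministic given
    frame order.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    frame_indices = np.arange(traj.n_frames)[::stride]
    m = len(frame_indices)
    if n_clusters > m:
        raise ValueError(f"n_clusters={n_clusters} exceeds {m} analysed frames")
    mat = pairwise_rmsd_matrix(traj, atom_subset, frame_indices)
    if m == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(mat, checks=False), method="average")
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    # relabel clusters by descending population (stable, deterministic)
    ids, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])

    populations, count_map, reps = {}, {}, {}
    for cid in sorted(set(labels)):
        members = np.nonzero(labels == cid)[0]
        count_map[cid] = int(len(members))
        populations[cid] = 100.0 * len(members) / m
        sums = mat[np.ix_(members, members)].sum(axis=1)
        medoid_local = members[int(np.argmin(sums))]
        reps[cid] = int(frame_indices[medoid_local])
    return ClusterResult(labels=labels, frame_indices=frame_indices,
                         populations=populations, counts=count_map,
                         representative_frames=reps)


def representative_structures(traj: Trajectory, result: ClusterResult,
                              group: str | None = None
                              ) -> dict[int, Structure]:
    """Structures at each cluster's medoid frame, optionally restricted to
    a named group (e.g. ``"receptor"`` for ensemble docking)."""
    out = {}
    for cid, frame in result.representative_frames.items():
        s = traj.structure.copy()
        s.set_coords(traj.frames[frame])
        if group is not None:
            s = s.subset(s.group_indices(group))
        out[cid] = s
    return out
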