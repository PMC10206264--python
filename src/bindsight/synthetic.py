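"""Seeded toy protein-ligand complexes and trajectories with known ground
truth.

The generator emulates the *outputs* of an MD study of an inhibitor bound
to a kinase: a poly-alanine-like receptor chain with named backbone and
side-chain atoms, a multi-atom ligand in a pocket, and coordinate frames in
which chosen hydrogen bonds are formed with a planted occupancy, chosen
heavy-atom contacts fluctuate around planted mean distances, and all other
atoms undergo approximately harmonic (isotropic Gaussian) fluctuation.

Frames are drawn i.i.d. — there is no integrator, thermostat or
autocorrelation.  That is sufficient for validating estimators that are
frame averages (occupancies, mean distances, frame-averaged energies,
RMSF) and is a deliberate simplification of real dynamics.  All randomness
flows from ``SyntheticSpec.seed`` through a single ``numpy`` PCG64
generator, so output is fully deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, Structure, Trajectory

__all__ = [
    "PlantedHBond",
    "PlantedContact",
    "SyntheticSpec",
    "generate_complex",
    "generate_trajectory",
    "generate_harmonic_trajectory",
    "default_planted_hbonds",
]

KB = 0.0019872041  # Boltzmann constant, kcal/mol/K


@dataclass(frozen=True)
class PlantedHBond:
    """A donor-H...acceptor triple planted at a chosen occupancy.

    In bound frames the donor-acceptor distance is ``bound_distance`` (with
    truncated Gaussian noise) and the acceptor-H-donor angle is uniform in
    [150, 180) degrees; in unbound frames the distance is
    ``unbound_distance`` and the angle uniform in [60, 110) degrees, so the
    standard geometric criterion (<3.5 A, >120 deg) classifies every frame
    unambiguously.
    """

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    target_occupancy: float
    bound_distance: float = 2.9
    unbound_distance: float = 5.5
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must be in [0, 1]")
        if not self.bound_distance + 3 * self.noise_sd < 3.5:
            raise ValueError("bound_distance + 3*noise_sd must stay below 3.5 A")
        if not self.unbound_distance - 3 * self.noise_sd > 3.5:
            raise ValueError("unbound_distance - 3*noise_sd must stay above 3.5 A")


@dataclass(frozen=True)
class PlantedContact:
    """A heavy-atom pair whose distance fluctuates about a planted mean."""

    atom_i: int
    atom_j: int
    mean_distance: float
    sd: float


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic complex and its trajectory."""

    n_receptor_residues: int = 20
    n_ligand_atoms: int = 8
    n_frames: int = 500
    planted_hbonds: list[PlantedHBond] = field(default_factory=list)
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    fluctuation_sd_per_atom: float = 0.15
    ligand_net_charge: float = 0.0
    frame_dt: float = 1.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor_residues < 1 or self.n_ligand_atoms < 1:
            raise ValueError("atom/residue counts must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.fluctuation_sd_per_atom < 0:
            raise ValueError("fluctuation sd must be nonnegative")


# per-atom-name parameters of the toy residue: (element, charge, sigma,
# epsilon, mass, born radius, backbone)
_RESIDUE_TEMPLATE = [
    ("N", "N", -0.40, 3.25, 0.170, 14.007, 1.55, True),
    ("H", "H", 0.30, 1.07, 0.016, 1.008, 1.20, True),
    ("CA", "C", 0.10, 3.40, 0.109, 12.011, 1.70, True),
    ("C", "C", 0.50, 3.40, 0.086, 12.011, 1.70, True),
    ("O", "O", -0.50, 2.96, 0.210, 15.999, 1.50, True),
    ("CB", "C", 0.00, 3.40, 0.109, 12.011, 1.70, False),
]

# local offsets (Angstrom) of residue atoms relative to the CA position
_RESIDUE_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.00]),
    "H": np.array([-1.20, 0.60, -1.02]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.30, 0.50, 0.00]),
    "O": np.array([1.90, 1.55, 0.00]),
    "CB": np.array([0.00, -1.30, 0.60]),
}

_CA_SPACING = 3.8  # Angstrom between consecutive CA atoms


def generate_complex(spec: SyntheticSpec) -> Structure:
    """Build the toy receptor chain plus a rigid ligand in a pocket.

    The receptor is a straight poly-alanine-like chain (backbone N, H, CA,
    C, O plus a CB side chain per residue) along x; the ligand is a ring of
    atoms placed on the side-chain face near the middle of the chain.  The
    construction is deterministic and self-avoiding by design (minimum
    interatomic separation > 1 A).
    """
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    serial = 1
    index_of: dict[tuple[int, str], int] = {}

    for res in range(spec.n_receptor_residues):
        ca = np.array([res * _CA_SPACING, 0.0, 0.0])
        for (name, element, q, sig, eps, mass, rgb, bb) in _RESIDUE_TEMPLATE:
            index_of[(res, name)] = len(atoms)
            atoms.append(Atom(
                serial=serial, name=name, element=element, residue_name="ALA",
                residue_index=res + 1, chain_id="A",
                position=ca + _RESIDUE_OFFSETS[name],
                charge=q, lj_sigma=sig, lj_epsilon=eps, mass=mass,
                gb_radius=rgb, is_backbone=bb))
            serial += 1
        i = lambda n: index_of[(res, n)]  # noqa: E731
        bonds += [(i("N"), i("H")), (i("N"), i("CA")), (i("CA"), i("C")),
                  (i("C"), i("O")), (i("CA"), i("CB"))]
        if res > 0:
            bonds.append((index_of[(res - 1, "C")], index_of[(res, "N")]))

    n_receptor = len(atoms)

    # ligand: ring of atoms in the pocket on the side-chain face (-y).
    # Roster: atom 0 = N donor, atom 1 = its H, then alternating O
    # (acceptors) and C so multiple hydrogen bonds can be planted.
    mid = (spec.n_receptor_residues - 1) / 2.0 * _CA_SPACING
    center = np.array([mid, -6.0, 0.5])
    n_lig = spec.n_ligand_atoms
    if n_lig == 1:
        lig_names = [("X1", "C", spec.ligand_net_charge, 3.40, 0.109,
                      12.011, 1.70)]
    else:
        lig_names = []
        for k in range(n_lig):
            if k == 0:
                lig_names.append((f"N{k + 1}", "N", -0.30, 3.25, 0.170,
                                  14.007, 1.55))
            elif k == 1:
                lig_names.append((f"H{k}", "H", 0.30, 1.07, 0.016,
                                  1.008, 1.20))
            elif k % 2 == 0:
                lig_names.append((f"O{k}", "O", -0.25, 2.96, 0.210,
                                  15.999, 1.50))
            else:
                lig_names.append((f"C{k}", "C", 0.25, 3.40, 0.109,
                                  12.011, 1.70))
    ring_n = max(n_lig - 1, 1) if n_lig > 1 else 1
    radius = max(1.4, 1.5 * ring_n / (2 * np.pi))
    for k, (name, element, q, sig, eps, mass, rgb) in enumerate(lig_names):
        if n_lig == 1:
            pos = center.copy()
        elif k == 1:  # hydrogen; repositioned 1.0 A off its donor below
            pos = center.copy()
        else:
            ring_pos = k if k == 0 else k - 1  # H excluded from the ring
            theta = 2 * np.pi * ring_pos / ring_n
            pos = center + radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        atoms.append(Atom(
            serial=serial, name=name, element=element, residue_name="LIG",
            residue_index=1, chain_id="B", position=pos,
            charge=q, lj_sigma=sig, lj_epsilon=eps, mass=mass,
            gb_radius=rgb, is_backbone=False))
        serial += 1
    if n_lig > 1:
        donor = atoms[n_receptor].position
        outward = donor - center
        outward = outward / np.linalg.norm(outward)
        atoms[n_receptor + 1].position = donor + 1.02 * outward  # N-H
        bonds.append((n_receptor, n_receptor + 1))  # N-H
        ring = [n_receptor] + list(range(n_receptor + 2, len(atoms)))
        if len(ring) == 2:
            bonds.append((ring[0], ring[1]))
        elif len(ring) > 2:
            bonds.extend(zip(ring, ring[1:] + ring[:1]))

    structure = Structure(
        atoms=atoms, bonds=bonds,
        groups={"receptor": set(range(n_receptor)),
                "ligand": set(range(n_receptor, len(atoms)))},
    )
    _check_self_avoiding(structure)
    return structure


def _check_self_avoiding(structure: Structure, min_sep: float = 1.0) -> None:
    coords = structure.coords
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # bonded pairs may legitimately sit at ~1 A (N-H)
    for a, b in structure.bonds:
        d[a, b] = d[b, a] = np.inf
    if d.min() <= min_sep:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise RuntimeError(
            f"generated geometry not self-avoiding: atoms {i} and {j} at "
            f"{d[i, j]:.2f} A")


def default_planted_hbonds(structure: Structure,
                           occupancies: list[float],
                           **kwargs) -> list[PlantedHBond]:
    """Convenience: plant one H-bond per requested occupancy.

    Donors are backbone N-H pairs of receptor residues near the middle of
    the chain; acceptors are distinct ligand O/N atoms, so the planted
    geometries never compete for the same atom.
    """
    rec = structure.group_indices("receptor")
    lig = structure.group_indices("ligand")
    donors = [(i, i + 1) for i in rec
              if structure.atoms[i].name == "N"
              and structure.atoms[i + 1].name == "H"]
    acceptors = [i for i in lig if structure.atoms[i].element in ("O", "N")
                 and structure.atoms[i].name != "N1"]
    if len(occupancies) > min(len(donors), len(acceptors)):
        raise ValueError("not enough donor/acceptor atoms for that many bonds")
    mid = len(donors) // 2
    bonds = []
    for k, occ in enumerate(occupancies):
        d, h = donors[(mid + k) % len(donors)]
        bonds.append(PlantedHBond(donor_index=d, hydrogen_index=h,
                                  acceptor_index=acceptors[k],
                                  target_occupancy=occ, **kwargs))
    return bonds


def _place_acceptor(donor: np.ndarray, hydrogen: np.ndarray,
                    distance: float, angle_deg: float,
                    toward: np.ndarray) -> np.ndarray:
    """Position an acceptor so that |donor-acceptor| = ``distance`` and the
    acceptor-H-donor angle (vertex at H) equals ``angle_deg``.

    The free azimuth is aimed at ``toward`` (the acceptor's resting
    position), which keeps planted geometries out of the receptor chain.
    """
    hd = donor - hydrogen
    r = np.linalg.norm(hd)
    u = hd / r
    v = toward - hydrogen
    v = v - (v @ u) * u  # azimuth direction, orthogonal to H->donor
    norm = np.linalg.norm(v)
    if norm < 1e-8:
        ref = (np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9
               else np.array([0.0, 1.0, 0.0]))
        v = np.cross(u, ref)
        norm = np.linalg.norm(v)
    v = v / norm
    alpha = np.radians(angle_deg)
    disc = distance ** 2 - (r * np.sin(alpha)) ** 2
    if disc <= 0:
        raise ValueError("infeasible H-bond geometry (distance < r_DH*sin)")
    ell = r * np.cos(alpha) + np.sqrt(disc)  # |H - acceptor|
    return hydrogen + ell * (np.cos(alpha) * u + np.sin(alpha) * v)


def generate_trajectory(structure: Structure, spec: SyntheticSpec) -> Trajectory:
    """Draw i.i.d. frames with planted H-bond and contact geometry.

    Per frame: all atoms are jittered isotropically; each planted contact's
    second atom is then moved along the pair axis to the sampled distance;
    each planted H-bond's acceptor is positioned to sampled bound/unbound
    geometry according to a Bernoulli draw at its target occupancy.  The
    ligand is otherwise rigid apart from the global jitter; planted
    acceptor atoms are exempt from that rigidity by construction.
    """
    rng = np.random.default_rng(spec.seed)
    base = structure.coords
    n = structure.n_atoms
    clearance = 2.3  # A; resample the free angle if a placement lands closer
    frames = np.empty((spec.n_frames, n, 3))
    for f in range(spec.n_frames):
        coords = base + rng.normal(0.0, spec.fluctuation_sd_per_atom, (n, 3))
        for c in spec.planted_contacts:
            target = c.mean_distance + rng.normal(0.0, c.sd)
            axis = coords[c.atom_j] - coords[c.atom_i]
            norm = np.linalg.norm(axis)
            coords[c.atom_j] = coords[c.atom_i] + axis / norm * target
        for hb in spec.planted_hbonds:
            bound = rng.random() < hb.target_occupancy
            noise = np.clip(rng.normal(0.0, hb.noise_sd),
                            -3 * hb.noise_sd, 3 * hb.noise_sd)
            dist = (hb.bound_distance if bound else hb.unbound_distance) + noise
            lo, hi = (150.0, 180.0) if bound else (60.0, 110.0)
            others = np.ones(n, dtype=bool)
            others[[hb.donor_index, hb.hydrogen_index, hb.acceptor_index]] = False
            best, best_sep = None, -np.inf
            for _ in range(20):
                angle = rng.uniform(lo, hi)
                pos = _place_acceptor(coords[hb.donor_index],
                                      coords[hb.hydrogen_index], dist, angle,
                                      base[hb.acceptor_index])
                sep = np.min(np.linalg.norm(coords[others] - pos, axis=1))
                if sep > best_sep:
                    best, best_sep = pos, sep
                if sep >= clearance:
                    break
            coords[hb.acceptor_index] = best
        frames[f] = coords
    times = spec.frame_dt * np.arange(spec.n_frames)
    return Trajectory(structure=structure, frames=frames, frame_times=times,
                      native_dt=spec.frame_dt)


def generate_harmonic_trajectory(n_atoms: int, spring_k: float,
                                 temperature: float, n_frames: int,
                                 seed: int, mass: float = 12.011
                                 ) -> Trajectory:
    """Exact Boltzmann samples of independent 3-D harmonic wells.

    Each Cartesian component is Gaussian with variance k_B*T/spring_k
    (``spring_k`` in kcal/mol/A^2), the closed form against which the
    quasi-harmonic entropy estimator is validated.
    """
    if spring_k <= 0:
        raise ValueError("spring_k must be positive")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_atoms, 3))
    centers[:, 0] = 5.0 * np.arange(n_atoms)
    sd = np.sqrt(KB * temperature / spring_k)
    frames = centers[None] + rng.normal(0.0, sd, (n_frames, n_atoms, 3))
    atoms = [Atom(serial=i + 1, name=f"C{i + 1}", element="C",
                  residue_name="HRM", residue_index=i + 1, chain_id="A",
                  position=centers[i], mass=mass, lj_sigma=3.4,
                  lj_epsilon=0.1, gb_radius=1.7)
             for i in range(n_atoms)]
    structure = Structure(atoms=atoms,
                          groups={"receptor": set(range(n_atoms))})
    return Trajectory(structure=structure, frames=frames,
                      frame_times=np.arange(n_frames, dtype=float),
                      native_dt=1.0)
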